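"""Energetics of endothelial breech by a deforming tumor cell.

A tumor cell crossing a capillary junction compresses the two adjoining
endothelial cells, modelled as incompressible neo-Hookean solids under
uniaxial compression.  The strain energy density per compressed cell is

    W = (G/2) * (lambda^2 + 2/lambda - 3),   lambda = 1 + eps,

with shear modulus ``G = E/3`` (Poisson ratio 1/2).  A round cell of
diameter ``d`` compresses each endothelial cell (length ``l``) by its
semi-minor axis, giving the undeformed strain ``eps_I = (d/2)/l``; a cell
elongated to aspect ``x = r/b`` presents a thinner profile and the strain
scales down to ``eps_II = eps_I / x``.  The full metastatic cycle
(intravasation plus extravasation) doubles the cost.

Elongation itself is paid for by breaking and re-forming actin bonds.
The monomer binding free energy is ``dG_B = k_B*T*ln(k_on*M/k_off)``; the
energy density tied up in bonds is ``W_act = (1 - f_act)*N_A*C_act*dG_B``
where ``f_act`` is the relative filamentous-actin content, and losses at
polymerisation efficiency ``eta_act`` leave a net deformation cost
``W_def = (1/eta_act - 1) * W_act``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .geometry import aspect_from_circularity

__all__ = [
    "EnergeticsParams",
    "EnergyProfile",
    "case1_strain",
    "case2_strain",
    "neo_hookean_uniaxial",
    "breech_energy_per_cycle",
    "monomer_binding_free_energy",
    "factin_fraction",
    "actin_bond_energy_density",
    "deformation_energy_density",
    "total_energy_profile",
    "elongation_to_inverse_circularity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnergeticsParams:
    """Physical parameters of the breech-energy model.

    Defaults reproduce the published benchmark calculation for a primary
    mammary epithelial cell crossing a HUVEC junction.

    Attributes
    ----------
    E : float
        Endothelial elastic modulus (Pa).  Default 10 kPa (AFM-measured
        HUVEC modulus).
    nu : float
        Poisson ratio; 0.5 for an incompressible solid.
    eta_br : float
        Mechanical efficiency of the breech (dimensionless, (0, 1]).
        Only used in ``as_written`` mode.
    eta_act : float
        Actin polymerisation efficiency (dimensionless, (0, 1]).
    C_act : float
        F-actin concentration in mol m^-3 (50 uM = 0.05).
    M : float
        G-actin monomer concentration (uM).
    k_on : float
        Polymerisation rate constant (uM^-1 s^-1).
    k_off : float
        Depolymerisation rate constant (s^-1).
    T : float
        Temperature (K).
    k_B, N_A : float
        Boltzmann and Avogadro constants.
    f_act_benchmark, c_benchmark : float
        Calibration anchor: relative f-actin content 0.8 at circularity
        0.7 (neutrophil cytoskeletal-rearrangement data).
    gamma : float or None
        Slope of the broken-bond fraction per unit aspect excess; if None
        it is derived from the benchmark anchor at construction.
    l_endo : float
        Endothelial cell length (um).
    d_epi : float
        Undeformed epithelial cell diameter (um).
    prefactor_mode : str
        ``"as_printed"`` (default): total per cycle 2*G*eps^2*(eps+3)/(eps+1),
        which reproduces the published 530/239 Pa numbers.  ``"as_written"``:
        per-crossing energy E/(6*eta_br)*eps^2*(eps+3)/(eps+1), doubled for
        the cycle.  The two coincide when eta_br = 0.5.
    log_base : str
        ``"e"`` (natural log, default) or ``"10"`` for the binding free
        energy logarithm.
    """

    E: float = 10_000.0
    nu: float = 0.5
    eta_br: float = 0.15
    eta_act: float = 0.15
    C_act: float = 0.05
    M: float = 10.0
    k_on: float = 11.6
    k_off: float = 1.0
    T: float = 310.0
    k_B: float = 1.381e-23
    N_A: float = 6.022e23
    f_act_benchmark: float = 0.8
    c_benchmark: float = 0.7
    gamma: float | None = None
    l_endo: float = 30.97
    d_epi: float = 10.62
    prefactor_mode: str = "as_printed"
    log_base: str = "e"

    def __post_init__(self) -> None:
        for name in ("E", "C_act", "M", "k_on", "k_off", "T", "k_B", "N_A",
                     "l_endo", "d_epi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("eta_br", "eta_act"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not (0 < self.f_act_benchmark <= 1):
            raise ValueError("f_act_benchmark must lie in (0, 1]")
        if not (0 < self.c_benchmark <= 1):
            raise ValueError("c_benchmark must lie in (0, 1]")
        if self.prefactor_mode not in ("as_printed", "as_written"):
            raise ValueError(f"unknown prefactor_mode {self.prefactor_mode!r}")
        if self.log_base not in ("e", "10"):
            raise ValueError(f"log_base must be 'e' or '10', got {self.log_base!r}")
        if self.gamma is None:
            x_bench = aspect_from_circularity(self.c_benchmark)
            object.__setattr__(
                self, "gamma", (1.0 - self.f_act_benchmark) / (x_bench - 1.0)
            )

    @property
    def G(self) -> float:
        """Shear modulus E / (2*(1 + nu)); E/3 for an incompressible solid."""
        return self.E / (2.0 * (1.0 + self.nu))

    @classmethod
    def from_config(cls, config: dict) -> "EnergeticsParams":
        """Build from a JSON-style dict; omitted keys keep their defaults.

        Accepts ``C_act_uM`` as an alternative to ``C_act`` (converted
        uM -> mol m^-3, i.e. x 1e-3).
        """
        config = dict(config)
        if "C_act_uM" in config:
            if "C_act" in config:
                raise ValueError("give either C_act or C_act_uM, not both")
            config["C_act"] = float(config.pop("C_act_uM")) * 1e-3
        known = {f.name for f in fields(cls)}
        unknown = set(config) - known
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**config)

    @classmethod
    def from_json(cls, path) -> "EnergeticsParams":
        with open(path) as fh:
            return cls.from_config(json.load(fh))

    def replace(self, **kwargs) -> "EnergeticsParams":
        if "gamma" not in kwargs and ("c_benchmark" in kwargs or "f_act_benchmark" in kwargs):
            kwargs["gamma"] = None  # re-derive from the new anchor
        return replace(self, **kwargs)


@dataclass(frozen=True)
class EnergyProfile:
    """Energy densities sampled over an inverse-circularity grid (all Pa)."""

    inverse_circularity: np.ndarray
    W_br_total: np.ndarray
    W_def: np.ndarray
    W_total: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "inverse_circularity", np.asarray(self.inverse_circularity, float)
        )
        object.__setattr__(self, "W_br_total", np.asarray(self.W_br_total, float))
        object.__setattr__(self, "W_def", np.asarray(self.W_def, float))
        if self.W_total is None:
            object.__setattr__(self, "W_total", self.W_br_total + self.W_def)
        else:
            object.__setattr__(self, "W_total", np.asarray(self.W_total, float))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "inverse_circularity": self.inverse_circularity,
                "W_br_total_Pa": self.W_br_total,
                "W_def_Pa": self.W_def,
                "W_total_Pa": self.W_total,
            }
        )


def case1_strain(d_epi: float, l_endo: float) -> float:
    """Endothelial strain for an undeformed (spherical) epithelial cell.

    Each adjoining endothelial cell of length ``l`` is compressed by the
    epithelial semi-minor axis ``d/2``: ``eps_I = (d/2) / l``.
    """
    if d_epi <= 0 or l_endo <= 0:
        raise ValueError("lengths must be strictly positive")
    eps = (d_epi / 2.0) / l_endo
    if eps >= 1:
        raise ValueError(
            f"strain {eps:.3g} >= 1: endothelial cell fully compressed, "
            "outside the model domain"
        )
    return eps


def case2_strain(eps1: float, x) -> float:
    """Strain after elongation to aspect ``x``: ``eps_II = eps_I / x``."""
    if not (0 < eps1 < 1):
        raise ValueError(f"case-I strain must lie in (0, 1), got {eps1}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 1):
        raise ValueError("aspect parameter must be >= 1")
    e = eps1 / x
    return e if e.ndim else float(e)


def neo_hookean_uniaxial(lam, G: float):
    """Neo-Hookean strain energy density under uniaxial stretch ``lam``.

    ``(G/2) * (lam^2 + 2/lam - 3)``; non-negative, zero only at lam = 1.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("principal stretch must be strictly positive")
    w = (G / 2.0) * (lam**2 + 2.0 / lam - 3.0)
    return w if w.ndim else float(w)


def _strain_form(eps):
    """eps^2 * (eps + 3) / (eps + 1); identical to lam^2 + 2/lam - 3 at lam = 1 + eps."""
    return eps**2 * (eps + 3.0) / (eps + 1.0)


def breech_energy_per_cycle(eps, params: EnergeticsParams | None = None):
    """Total breech energy density for one metastatic cycle (Pa).

    Covers intravasation plus extravasation.  In ``as_printed`` mode the
    total is ``2 * G * eps^2 * (eps+3)/(eps+1)`` — two junction crossings,
    each compressing two adjoining endothelial cells storing (G/2)*f(eps)
    apiece.  In ``as_written`` mode each crossing costs
    ``E/(6*eta_br) * f(eps)`` and the cycle doubles it.
    """
    if params is None:
        params = EnergeticsParams()
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0) or np.any(eps >= 1):
        raise ValueError("strain must lie in [0, 1)")
    if params.prefactor_mode == "as_printed":
        w = 2.0 * params.G * _strain_form(eps)
    else:
        w = 2.0 * (params.E / (6.0 * params.eta_br)) * _strain_form(eps)
    return w if w.ndim else float(w)


def monomer_binding_free_energy(params: EnergeticsParams | None = None) -> float:
    """G-actin monomer binding free energy ``k_B*T*log(k_on*M/k_off)`` (J)."""
    if params is None:
        params = EnergeticsParams()
    ratio = params.k_on * params.M / params.k_off
    if ratio <= 1:
        warnings.warn(
            f"k_on*M/k_off = {ratio:.3g} <= 1: non-positive binding energy, "
            "outside the model scope",
            stacklevel=2,
        )
    log = math.log if params.log_base == "e" else math.log10
    return params.k_B * params.T * log(ratio)


def factin_fraction(x, params: EnergeticsParams | None = None):
    """Relative f-actin content of a cell elongated to aspect ``x``.

    Linear in the aspect excess, ``f_act = clip(1 - gamma*(x - 1), 0, 1)``,
    with the slope anchored so that f_act = 0.8 at circularity 0.7 under
    the default benchmark.
    """
    if params is None:
        params = EnergeticsParams()
    x = np.asarray(x, dtype=float)
    if np.any(x < 1):
        raise ValueError("aspect parameter must be >= 1")
    f = np.clip(1.0 - params.gamma * (x - 1.0), 0.0, 1.0)
    return f if f.ndim else float(f)


def actin_bond_energy_density(f_act, params: EnergeticsParams | None = None):
    """Energy density of broken actin bonds, ``(1 - f_act)*N_A*C_act*dG_B`` (Pa)."""
    if params is None:
        params = EnergeticsParams()
    f_act = np.asarray(f_act, dtype=float)
    if np.any(f_act < 0) or np.any(f_act > 1):
        raise ValueError("f_act must lie in [0, 1]")
    w = (1.0 - f_act) * params.N_A * params.C_act * monomer_binding_free_energy(params)
    return w if w.ndim else float(w)


def deformation_energy_density(W_act, eta_act: float):
    """Net deformation cost ``(1/eta_act - 1) * W_act`` (Pa)."""
    if not (0 < eta_act <= 1):
        raise ValueError(f"eta_act must lie in (0, 1], got {eta_act}")
    W_act = np.asarray(W_act, dtype=float)
    w = (1.0 / eta_act - 1.0) * W_act
    return w if w.ndim else float(w)


def total_energy_profile(
    c_inv_grid, params: EnergeticsParams | None = None
) -> EnergyProfile:
    """Breech, deformation and total energy densities over a C^-1 grid.

    For each inverse circularity the aspect ``x`` is found by numeric
    inversion, the strain is scaled to ``eps_I / x`` and the cycle breech
    energy evaluated; the deformation cost follows from the broken-bond
    fraction at that aspect.
    """
    if params is None:
        params = EnergeticsParams()
    grid = np.asarray(c_inv_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if np.any(grid < 1):
        raise ValueError("inverse circularity must be >= 1")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")

    eps1 = case1_strain(params.d_epi, params.l_endo)
    x = np.array([aspect_from_circularity(1.0 / c) for c in grid])
    eps = case2_strain(eps1, x)
    w_br = breech_energy_per_cycle(eps, params)
    f_act = factin_fraction(x, params)
    w_def = deformation_energy_density(actin_bond_energy_density(f_act, params),
                                       params.eta_act)
    return EnergyProfile(
        inverse_circularity=grid,
        W_br_total=np.atleast_1d(w_br),
        W_def=np.atleast_1d(w_def),
    )


def elongation_to_inverse_circularity(elong, baseline_c_inv: float = 1.0):
    """Map an elongation value back to inverse circularity.

    Inverts the elongation definition: ``C^-1 = (1 + elong) * baseline``,
    where ``baseline`` is the off-vessel mean inverse circularity.  Values
    that fall below the physical floor of 1 are clamped (logged).
    """
    if baseline_c_inv < 1:
        raise ValueError(f"baseline inverse circularity must be >= 1, got {baseline_c_inv}")
    elong = np.asarray(elong, dtype=float)
    if np.any(elong <= -1):
        raise ValueError("elongation must exceed -1")
    c_inv = (1.0 + elong) * baseline_c_inv
    if np.any(c_inv < 1):
        logger.warning(
            "inverse circularity below 1 for %d value(s); clamped to 1",
            int(np.sum(c_inv < 1)),
        )
        c_inv = np.maximum(c_inv, 1.0)
    return c_inv if c_inv.ndim else float(c_inv)
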