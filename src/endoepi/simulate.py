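"""Synthetic co-culture measurement tables and labelled images.

The generator emulates what the quantification pipeline consumes: per-cell
measurement tables with the statistical structure of a co-culture, and
composite images of elliptical epithelial cells around endothelial tubes,
with exact ground truth for every cell.

Per condition the structure is: on/off-vessel flags are Bernoulli with the
condition's association probability; off-vessel cells sit near the round
baseline (inverse circularity ``1 + |N(0, sd)|``); on-vessel cells draw an
elongation value from a shifted lognormal (long right tail, matching the
wide elongation distributions of metastatic lines) and receive
``C^-1 = (1 + elong) * baseline``, converted to ellipse axes at constant
volume; fluorescence is proportional to projected area.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .geometry import aspect_from_circularity, projected_area

__all__ = [
    "ConditionArchetype",
    "generate_measurements",
    "generate_coculture_image",
    "shipped_archetypes",
]

logger = logging.getLogger(__name__)

_Z75 = 0.6744897501960817  # Phi^-1(0.75)


@dataclass(frozen=True)
class ConditionArchetype:
    """Distributional description of one cell line / treatment condition.

    Elongation of on-vessel cells is parameterised by its median and IQR
    under the chosen family (``"shifted_lognormal"`` with shape
    ``elong_sigma``, or ``"normal"``); an IQR of zero degenerates to the
    median.  The off-vessel baseline inverse circularity is
    ``1 + |N(0, c_inv_off_sd)|``, and cell diameters are normal (um),
    truncated to stay positive.
    """

    name: str
    p_on: float
    elong_median: float
    elong_iqr: float
    elong_family: str = "shifted_lognormal"
    elong_sigma: float = 0.75
    c_inv_off_sd: float = 0.02
    diameter_mean_um: float = 10.62
    diameter_sd_um: float = 2.37
    intensity_per_area: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_on <= 1.0):
            raise ValueError(f"p_on must lie in [0, 1], got {self.p_on}")
        if self.elong_iqr < 0:
            raise ValueError("elongation IQR must be non-negative")
        if self.elong_family not in ("shifted_lognormal", "normal"):
            raise ValueError(f"unknown elongation family {self.elong_family!r}")
        if self.elong_sigma <= 0:
            raise ValueError("elong_sigma must be positive")
        if self.c_inv_off_sd < 0 or self.diameter_mean_um <= 0 or self.diameter_sd_um < 0:
            raise ValueError("invalid baseline/diameter distribution spec")
        if self.intensity_per_area <= 0:
            raise ValueError("intensity_per_area must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionArchetype":
        return cls(**d)

    def sample_elongation(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.elong_iqr == 0:
            return np.full(n, self.elong_median)
        if self.elong_family == "normal":
            sd = self.elong_iqr / (2.0 * _Z75)
            return rng.normal(self.elong_median, sd, n)
        # shifted lognormal: loc + s*exp(sigma*Z); median = loc + s,
        # IQR = s*(e^{z*sigma} - e^{-z*sigma})
        s = self.elong_iqr / (
            math.exp(_Z75 * self.elong_sigma) - math.exp(-_Z75 * self.elong_sigma)
        )
        loc = self.elong_median - s
        return loc + s * np.exp(self.elong_sigma * rng.standard_normal(n))


def _resolve_rng(archetype: ConditionArchetype, seed) -> np.random.Generator:
    if seed is None:
        seed = archetype.seed
    if seed is None:
        raise ValueError("a seed is required (archetype.seed or the seed argument)")
    return np.random.default_rng(seed)


def _positive_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, floor: float
) -> np.ndarray:
    """Normal draws with sub-floor values redrawn (truncation by rejection)."""
    out = rng.normal(mean, sd, n)
    for _ in range(100):
        bad = out <= floor
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.maximum(out, floor)


def _cell_shapes(
    archetype: ConditionArchetype, n_cells: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw per-cell geometry: on/off, radii, inverse circularity, axes, fluorescence."""
    on = rng.random(n_cells) < archetype.p_on
    diam = _positive_normal(
        rng, archetype.diameter_mean_um, archetype.diameter_sd_um, n_cells, floor=1.0
    )
    r = diam / 2.0
    baseline = 1.0 + np.abs(rng.normal(0.0, archetype.c_inv_off_sd, n_cells))
    c_inv = baseline.copy()
    n_on = int(on.sum())
    if n_on:
        elong = archetype.sample_elongation(n_on, rng)
        c_inv[on] = np.maximum(1.0, (1.0 + elong) * baseline[on])
    x = np.array([aspect_from_circularity(1.0 / c) for c in c_inv])
    return pd.DataFrame(
        {
            "condition": archetype.name,
            "cell_id": [f"{archetype.name}-{i:04d}" for i in range(n_cells)],
            "on_vessel": on,
            "r_um": r,
            "aspect": x,
            "major_axis_um": 2.0 * r * x**2,
            "minor_axis_um": 2.0 * r / x,
            "fluorescence": archetype.intensity_per_area * projected_area(r, x),
        }
    )


def generate_measurements(
    archetype: ConditionArchetype, n_cells: int, seed: int | None = None
) -> pd.DataFrame:
    """Generate a per-cell measurement table for one condition.

    Reproducible for a fixed seed.  Columns match the quantification
    pipeline's input contract (condition, cell_id, on_vessel,
    major/minor_axis_um, fluorescence).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = _resolve_rng(archetype, seed)
    df = _cell_shapes(archetype, n_cells, rng)
    return df.drop(columns=["r_um", "aspect"])


def _vessel_path(
    shape: tuple[int, int], rng: np.random.Generator, n_knots: int = 4
):
    """A smooth random tube centreline spanning the canvas left to right."""
    from scipy.interpolate import CubicSpline

    h, w = shape
    xs = np.linspace(0, w - 1, n_knots)
    ys = rng.uniform(0.25 * h, 0.75 * h, n_knots)
    spline = CubicSpline(xs, ys)
    cols = np.linspace(0, w - 1, 4 * w)
    rows = spline(cols)
    tang = np.arctan2(spline(cols, 1), 1.0)  # angle of the local tangent
    keep = (rows >= 0) & (rows <= h - 1)
    return rows[keep], cols[keep], tang[keep]


def generate_coculture_image(
    archetype: ConditionArchetype,
    shape: tuple[int, int] = (512, 512),
    n_cells: int = 40,
    seed: int | None = None,
    um_per_px: float = 1.6,
    vessel_width_um: float | None = None,
    peak: float = 10_000.0,
    noise_sigma_frac: float = 0.01,
    max_retries: int = 50,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a synthetic co-culture image pair with exact ground truth.

    Returns ``(intensity, vessel_mask, ground_truth)``: a float intensity
    channel, a boolean tube mask, and a measurement table for the cells
    actually placed.  On-vessel cells sit on the tube with their major
    axis along the local tangent; off-vessel cells are kept clear of the
    tube.  Every cell is painted at the same per-pixel brightness, so the
    image intensity split equals the ground-truth fluorescence split.
    Cells that cannot be placed after ``max_retries`` attempts are dropped
    (logged) and do not appear in the ground truth.
    """
    from scipy.ndimage import distance_transform_edt
    from skimage.draw import ellipse as draw_ellipse
    from skimage.morphology import dilation, disk

    rng = _resolve_rng(archetype, seed)
    h, w = shape

    if vessel_width_um is None:
        vessel_width_um = float(np.clip(rng.normal(30.97, 13.34), 10.0, None))
    width_px = max(3.0, vessel_width_um / um_per_px)

    rows, cols, tang = _vessel_path(shape, rng)
    mask = np.zeros(shape, dtype=bool)
    mask[np.round(rows).astype(int), np.round(cols).astype(int)] = True
    mask = dilation(mask, disk(int(round(width_px / 2.0))))

    intensity = np.zeros(shape, dtype=float)
    if n_cells == 0:
        gt = pd.DataFrame(columns=["condition", "cell_id", "on_vessel",
                                   "major_axis_um", "minor_axis_um", "fluorescence"])
    else:
        cells = _cell_shapes(archetype, n_cells, rng)
        dist_off = distance_transform_edt(~mask)
        pixel_value = 0.8 * peak
        placed_rows = []
        for rec in cells.itertuples(index=False):
            a_px = max(1.0, (rec.major_axis_um / 2.0) / um_per_px)
            b_px = max(1.0, (rec.minor_axis_um / 2.0) / um_per_px)
            margin = a_px + 2.0
            spot = None
            for _ in range(max_retries):
                if rec.on_vessel:
                    i = int(rng.integers(len(rows)))
                    max_off = max(0.0, width_px / 2.0 - b_px - 1.0)
                    off = rng.uniform(-max_off, max_off)
                    angle = tang[i]
                    rr = rows[i] + off * math.cos(angle)
                    cc = cols[i] - off * math.sin(angle)
                else:
                    rr = rng.uniform(margin, h - 1 - margin)
                    cc = rng.uniform(margin, w - 1 - margin)
                    angle = rng.uniform(-math.pi, math.pi)
                    if dist_off[int(rr), int(cc)] <= a_px + 3.0:
                        continue
                if margin <= rr <= h - 1 - margin and margin <= cc <= w - 1 - margin:
                    spot = (rr, cc, angle)
                    break
            if spot is None:
                logger.warning("dropped cell %s after %d placement retries",
                               rec.cell_id, max_retries)
                continue
            rr, cc, angle = spot
            # skimage's rotation is clockwise in (row, col); negate to align
            # the major axis with the tangent direction (sin a, cos a)
            pix_r, pix_c = draw_ellipse(rr, cc, b_px, a_px, shape=shape, rotation=-angle)
            intensity[pix_r, pix_c] += pixel_value
            row = rec._asdict()
            row["fluorescence"] = pixel_value * len(pix_r)
            placed_rows.append(row)
        gt = pd.DataFrame(placed_rows)
        if len(gt):
            gt = gt.drop(columns=["r_um", "aspect"])

    if noise_sigma_frac > 0:
        intensity += rng.normal(0.0, noise_sigma_frac * peak, shape)
        np.clip(intensity, 0.0, None, out=intensity)
    return intensity, mask, gt


# Printed condition medians: untreated MDA-MB-231 association/elongation
# 0.93/0.66, docetaxel 20 uM 0.58/0.16, docetaxel 50 uM 0.54/-0.0018, HMEC
# elongation -0.0026; HMEC association 0.29 from the 3.2-fold contrast with
# MDA-MB-231.  Remaining values (intermediate lines, all IQRs) are
# unpublished and set to plausible figures ordered by invasiveness.
_SHIPPED = [
    dict(name="HMEC", p_on=0.29, elong_median=-0.0026, elong_iqr=0.04),
    dict(name="MCF-10A", p_on=0.35, elong_median=0.004, elong_iqr=0.05),
    dict(name="SkBr3", p_on=0.45, elong_median=0.02, elong_iqr=0.06),
    dict(name="MCF-7", p_on=0.50, elong_median=0.03, elong_iqr=0.06),
    dict(name="MDA-MB-468", p_on=0.60, elong_median=0.08, elong_iqr=0.12),
    dict(name="MDA-MB-231", p_on=0.93, elong_median=0.66, elong_iqr=0.60),
    dict(name="MDA-MB-231+docetaxel-20", p_on=0.58, elong_median=0.16, elong_iqr=0.30),
    dict(name="MDA-MB-231+docetaxel-50", p_on=0.54, elong_median=-0.0018, elong_iqr=0.08),
]


def shipped_archetypes() -> list[ConditionArchetype]:
    """The six cell-line archetypes plus the two docetaxel treatment conditions."""
    return [ConditionArchetype(**d) for d in _SHIPPED]


def load_archetypes(path) -> list[ConditionArchetype]:
    """Read a JSON list of archetype specs."""
    with open(path) as fh:
        specs = json.load(fh)
    if isinstance(specs, dict):
        specs = [specs]
    return [ConditionArchetype.from_dict(s) for s in specs]
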