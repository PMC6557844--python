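"""Volume-conserving prolate-spheroid geometry of a deforming cell.

An epithelial cell of equivalent-sphere radius ``r`` that elongates at
constant volume into a prolate spheroid with semi-major axis ``a`` and
semi-minor axis ``b`` satisfies ``a * b**2 == r**3``.  The single aspect
parameter ``x = r / b >= 1`` then fixes the whole shape:
``b = r / x`` and ``a = r * x**2``.

Circularity of the projected ellipse is defined from its area ``A`` and
perimeter ``P`` as ``C = 4*pi*A / P**2``, with ``P`` evaluated by
Ramanujan's first approximation.  ``C`` decreases monotonically from 1
(sphere) as the cell elongates, so the map ``x -> C(x)`` can be inverted
numerically by bracketed root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SpheroidShape",
    "ellipse_perimeter",
    "circularity_from_axes",
    "circularity_from_aspect",
    "aspect_from_circularity",
    "axes_from_aspect",
    "projected_area",
]

#: Upper end of the bracketing interval for the numeric inversion of the
#: circularity relation.  C(50) ~ 4e-8; far beyond any observed shape.
_ASPECT_BRACKET = (1.0, 50.0)


@dataclass(frozen=True)
class SpheroidShape:
    """A constant-volume prolate spheroid.

    Parameters
    ----------
    r : float
        Equivalent-sphere radius (um).
    a : float
        Semi-major axis (um).
    b : float
        Semi-minor axis (um).
    x : float
        Aspect parameter ``r / b`` (dimensionless, >= 1).
    """

    r: float
    a: float
    b: float
    x: float

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.a >= self.b):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if self.x < 1:
            raise ValueError(f"aspect parameter must be >= 1, got {self.x}")
        if abs(self.a * self.b**2 - self.r**3) > 1e-9 * self.r**3:
            raise ValueError(
                "volume not conserved: a*b^2 = "
                f"{self.a * self.b**2:.9g} != r^3 = {self.r**3:.9g}"
            )

    @property
    def volume(self) -> float:
        """Cell volume (4/3)*pi*a*b^2 = (4/3)*pi*r^3 (um^3)."""
        return 4.0 / 3.0 * math.pi * self.a * self.b**2


def _check_axes(a, b) -> None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0) or np.any(a <= 0):
        raise ValueError("axes must be strictly positive")
    if np.any(a < b):
        raise ValueError("semi-major axis must satisfy a >= b (prolate only)")


def ellipse_perimeter(a, b):
    """Perimeter of an ellipse by Ramanujan's first approximation.

    ``P = pi * (3*(a + b) - sqrt((3a + b) * (a + 3b)))``; exact ``2*pi*r``
    for a circle and accurate to well under 0.5% for aspect ratios up to 20.
    """
    _check_axes(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    p = np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))
    return p if p.ndim else float(p)


def circularity_from_axes(a, b):
    """Circularity ``C = 4*pi*A / P**2`` of the projected ellipse.

    ``A = pi*a*b`` and ``P`` is the Ramanujan perimeter; ``C`` equals 1
    iff ``a == b`` and is strictly below 1 otherwise.
    """
    _check_axes(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = 4.0 * np.pi**2 * a * b / ellipse_perimeter(a, b) ** 2
    return c if c.ndim else float(c)


def circularity_from_aspect(x):
    """Circularity as a function of the aspect parameter ``x = r/b``.

    ``C(x) = 4*x^3 / (3*(x^3 + 1) - sqrt((3*x^3 + 1)*(x^3 + 3)))**2``,
    obtained by substituting the constant-volume axes into the axis form;
    strictly decreasing on ``x >= 1`` with ``C(1) = 1``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 1):
        raise ValueError("aspect parameter must be >= 1 (prolate shapes only)")
    x3 = x**3
    denom = 3.0 * (x3 + 1.0) - np.sqrt((3.0 * x3 + 1.0) * (x3 + 3.0))
    c = 4.0 * x3 / denom**2
    return c if c.ndim else float(c)


def aspect_from_circularity(c: float) -> float:
    """Invert the circularity relation: the unique ``x >= 1`` with ``C(x) = c``.

    Bracketed root search (Brent) on ``x in [1, 50]``; the residual
    ``|C(x) - c|`` is driven below 1e-12.
    """
    c = float(c)
    if not (0.0 < c <= 1.0):
        raise ValueError(f"circularity must lie in (0, 1], got {c}")
    if c == 1.0:
        return 1.0
    lo, hi = _ASPECT_BRACKET
    if circularity_from_aspect(hi) > c:
        raise ValueError(f"circularity {c} below invertible range (x > {hi})")
    return brentq(lambda x: circularity_from_aspect(x) - c, lo, hi, xtol=1e-13, rtol=1e-15)


def axes_from_aspect(r: float, x: float) -> SpheroidShape:
    """Axes of the constant-volume spheroid at aspect ``x``: ``b = r/x``, ``a = r*x^2``."""
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if x < 1:
        raise ValueError(f"aspect parameter must be >= 1, got {x}")
    return SpheroidShape(r=float(r), a=float(r) * x**2, b=float(r) / x, x=float(x))


def projected_area(r, x):
    """Projected area ``A = pi * r**2 * x`` of the spheroid (um^2)."""
    r = np.asarray(r, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    if np.any(x < 1):
        raise ValueError("aspect parameter must be >= 1")
    a = np.pi * r**2 * x
    return a if a.ndim else float(a)
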