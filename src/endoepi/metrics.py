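"""Interaction metrics for epithelial-endothelial co-cultures.

Two parameters quantify how tumor cells behave around endothelial tubes:

* **EEA** (epithelial-endothelial association): the fraction of epithelial
  fluorescence located on the vessels, ``Fl_on / Fl_total``.
* **Elongation**: the inverse-circularity of each on-vessel cell,
  normalised by the mean inverse circularity of the condition's
  off-vessel cells, ``(C_on^-1 - mean(C_off^-1)) / mean(C_off^-1)``.

Per-condition summaries collect both, and the 2-parameter index places
each condition as a rectangle spanning the interquartile ranges of
association (x) and elongation (y) — metastatic phenotypes sit to the
upper right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import circularity_from_axes

__all__ = [
    "CellRecord",
    "ConditionSummary",
    "load_measurements",
    "inverse_circularity",
    "elongation",
    "eea_from_table",
    "eea_from_image",
    "summarize_condition",
    "summarize_table",
    "two_parameter_index",
]

logger = logging.getLogger(__name__)

#: Canonical measurement-table columns.
TABLE_COLUMNS = [
    "condition",
    "cell_id",
    "on_vessel",
    "major_axis_um",
    "minor_axis_um",
    "fluorescence",
]


@dataclass(frozen=True)
class CellRecord:
    """One measured epithelial cell."""

    condition: str
    cell_id: str
    on_vessel: bool
    major_axis: float
    minor_axis: float
    fluorescence: float | None = None

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError(
                f"require major >= minor > 0, got {self.major_axis}, {self.minor_axis}"
            )


@dataclass(frozen=True)
class ConditionSummary:
    """Interaction summary for one cell line / treatment condition."""

    condition: str
    eea: float
    n_on: int
    n_off: int
    elong_median: float
    elong_q1: float
    elong_q3: float
    mean_c_inv_off: float
    assoc_q1: float = float("nan")
    assoc_q3: float = float("nan")
    ecdf_points: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.eea <= 1.0):
            raise ValueError(f"EEA must lie in [0, 1], got {self.eea}")
        if not (self.elong_q1 <= self.elong_median <= self.elong_q3):
            raise ValueError("elongation quartiles out of order")


def load_measurements(path_or_df) -> pd.DataFrame:
    """Load a per-cell measurement table, canonicalising axes.

    Rows whose axes are reversed (minor > major) are swapped; rows with a
    non-positive axis are rejected with a logged reason.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df)
    missing = {"condition", "on_vessel", "major_axis_um", "minor_axis_um"} - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    if "cell_id" not in df.columns:
        df["cell_id"] = [f"cell{i}" for i in range(len(df))]
    if "fluorescence" not in df.columns:
        df["fluorescence"] = np.nan

    bad = (df["major_axis_um"] <= 0) | (df["minor_axis_um"] <= 0)
    if bad.any():
        logger.warning("rejecting %d record(s) with non-positive axes", int(bad.sum()))
        df = df.loc[~bad].copy()

    swapped = df["minor_axis_um"] > df["major_axis_um"]
    if swapped.any():
        lo = df.loc[swapped, "major_axis_um"].to_numpy()
        df.loc[swapped, "major_axis_um"] = df.loc[swapped, "minor_axis_um"].to_numpy()
        df.loc[swapped, "minor_axis_um"] = lo
    df["on_vessel"] = df["on_vessel"].map(_to_bool)
    return df.reset_index(drop=True)


def _to_bool(v) -> bool:
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("on", "true", "1", "yes"):
            return True
        if s in ("off", "false", "0", "no"):
            return False
        raise ValueError(f"unrecognised on/off flag {v!r}")
    return bool(v)


def inverse_circularity(major, minor):
    """Inverse circularity ``C^-1 = P^2 / (4*pi*A)`` of a measured ellipse.

    Ranges from 1 (perfect circle) upward; axes are full lengths or
    semi-axes interchangeably (the ratio is scale-invariant).
    """
    c = circularity_from_axes(np.asarray(major, float) / 2.0,
                              np.asarray(minor, float) / 2.0)
    # guard against C marginally above 1 from rounding on perfect circles
    inv = np.maximum(1.0 / np.asarray(c, float), 1.0)
    return inv if inv.ndim else float(inv)


def elongation(c_inv_on, mean_c_inv_off: float):
    """Normalised shape change of on-vessel cells relative to the off baseline."""
    if mean_c_inv_off < 1:
        raise ValueError(
            f"baseline mean inverse circularity must be >= 1, got {mean_c_inv_off}"
        )
    c_inv_on = np.asarray(c_inv_on, dtype=float)
    e = (c_inv_on - mean_c_inv_off) / mean_c_inv_off
    return e if e.ndim else float(e)


def eea_from_table(records: pd.DataFrame) -> float:
    """Association from a measurement table: on-vessel share of fluorescence.

    Falls back to the on-vessel cell-count fraction when no fluorescence
    was recorded (logged).
    """
    if len(records) == 0:
        raise ValueError("empty measurement table")
    on = records["on_vessel"].astype(bool).to_numpy()
    fl = records.get("fluorescence")
    if fl is not None and np.isfinite(fl.to_numpy(dtype=float)).all() and (fl > 0).any():
        fl = fl.to_numpy(dtype=float)
        return float(fl[on].sum() / fl.sum())
    logger.info("no fluorescence recorded; EEA falls back to cell-count ratio")
    return float(on.mean())


def eea_from_image(
    intensity: np.ndarray,
    vessel_mask: np.ndarray,
    background: float = 0.0,
    contact_radius: int = 1,
) -> float:
    """Association from an image pair: intensity share on the outlined vessels.

    The vessel mask is dilated by ``contact_radius`` pixels (physical
    contact), the constant ``background`` is subtracted from the intensity
    channel with negative residuals clipped to zero, and the EEA is the
    within-outline intensity over the whole-frame intensity.
    """
    from skimage.morphology import dilation, disk

    intensity = np.asarray(intensity, dtype=float)
    vessel_mask = np.asarray(vessel_mask)
    if intensity.shape != vessel_mask.shape:
        raise ValueError(
            f"shape mismatch: intensity {intensity.shape} vs mask {vessel_mask.shape}"
        )
    uniq = np.unique(vessel_mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("vessel mask must be binary")
    mask = vessel_mask.astype(bool)
    if contact_radius > 0:
        mask = dilation(mask, disk(contact_radius))

    signal = np.clip(intensity - background, 0.0, None)
    total = signal.sum()
    if total == 0:
        return 0.0
    return float(signal[mask].sum() / total)


def summarize_condition(
    records: pd.DataFrame,
    per_image_eea: list[float] | np.ndarray | None = None,
    condition: str | None = None,
) -> ConditionSummary:
    """Per-condition summary: EEA, elongation quartiles, ECDF, baseline.

    The elongation baseline is the mean inverse circularity of the
    condition's off-vessel cells; at least two off-vessel cells are
    required for it to be defined.
    """
    records = load_measurements(records)
    if condition is None:
        conds = records["condition"].unique()
        if len(conds) != 1:
            raise ValueError(
                "table holds multiple conditions; pass `condition` or use summarize_table"
            )
        condition = str(conds[0])
    else:
        records = records[records["condition"] == condition]

    on = records[records["on_vessel"]]
    off = records[~records["on_vessel"]]
    if len(off) < 2:
        raise ValueError(
            f"condition {condition!r}: baseline undefined (need >= 2 off-vessel cells)"
        )

    c_inv_off = inverse_circularity(off["major_axis_um"], off["minor_axis_um"])
    mean_off = float(np.mean(c_inv_off))
    c_inv_on = inverse_circularity(on["major_axis_um"], on["minor_axis_um"])
    elong = np.atleast_1d(elongation(c_inv_on, mean_off))

    if elong.size:
        q1, med, q3 = np.quantile(elong, [0.25, 0.5, 0.75])  # type-7 linear
        order = np.sort(elong)
        ecdf = list(zip(order.tolist(), (np.arange(1, elong.size + 1) / elong.size).tolist()))
    else:
        q1 = med = q3 = float("nan")
        ecdf = []

    eea = eea_from_table(records)
    if per_image_eea is not None and len(per_image_eea) > 0:
        a1, a3 = np.quantile(np.asarray(per_image_eea, float), [0.25, 0.75])
    else:
        a1 = a3 = float("nan")

    return ConditionSummary(
        condition=condition,
        eea=eea,
        n_on=int(len(on)),
        n_off=int(len(off)),
        elong_median=float(med),
        elong_q1=float(q1),
        elong_q3=float(q3),
        mean_c_inv_off=mean_off,
        assoc_q1=float(a1),
        assoc_q3=float(a3),
        ecdf_points=ecdf,
    )


def summarize_table(
    records: pd.DataFrame,
    per_image_eea: dict[str, list[float]] | None = None,
) -> list[ConditionSummary]:
    """Summarise every condition in a mixed table; failures are logged and skipped."""
    records = load_measurements(records)
    out = []
    for cond, grp in records.groupby("condition", sort=False):
        eeas = (per_image_eea or {}).get(cond)
        try:
            out.append(summarize_condition(grp, per_image_eea=eeas, condition=str(cond)))
        except ValueError as exc:
            logger.warning("skipping condition %r: %s", cond, exc)
    return out


def _box(s: ConditionSummary) -> tuple[float, float, float, float]:
    """(x0, x1, y0, y1) of the condition's IQR rectangle; EEA point if no quartiles."""
    if np.isnan(s.assoc_q1) or np.isnan(s.assoc_q3):
        x0 = x1 = s.eea
    else:
        x0, x1 = s.assoc_q1, s.assoc_q3
    return x0, x1, s.elong_q1, s.elong_q3


def _overlap_fraction(b1, b2) -> float:
    """Intersection-over-union of two axis-aligned rectangles (degenerate-safe)."""
    ix = max(0.0, min(b1[1], b2[1]) - max(b1[0], b2[0]))
    iy = max(0.0, min(b1[3], b2[3]) - max(b1[2], b2[2]))
    a1 = (b1[1] - b1[0]) * (b1[3] - b1[2])
    a2 = (b2[1] - b2[0]) * (b2[3] - b2[2])
    union = a1 + a2 - ix * iy
    if union == 0:
        return 1.0 if b1 == b2 else 0.0
    return ix * iy / union


def two_parameter_index(summaries: list[ConditionSummary]) -> dict:
    """The 2-parameter phenotype index: IQR boxes, overlaps and centroid shifts.

    Returns a dict with per-condition boxes
    ``{condition: {assoc: [q1, q3], elong: [q1, q3], centroid: [x, y]}}``
    plus pairwise IoU overlap fractions and centroid distances.
    """
    if not summaries:
        raise ValueError("need at least one condition summary")
    boxes, index = {}, {}
    for s in summaries:
        b = _box(s)
        boxes[s.condition] = b
        index[s.condition] = {
            "assoc": [b[0], b[1]],
            "elong": [b[2], b[3]],
            "centroid": [(b[0] + b[1]) / 2.0, (b[2] + b[3]) / 2.0],
        }
    pairwise = {}
    names = list(boxes)
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            b1, b2 = boxes[n1], boxes[n2]
            c1 = np.array(index[n1]["centroid"])
            c2 = np.array(index[n2]["centroid"])
            pairwise[f"{n1}|{n2}"] = {
                "overlap_fraction": _overlap_fraction(b1, b2),
                "centroid_distance": float(np.hypot(*(c1 - c2))),
            }
    return {"conditions": index, "pairwise": pairwise}
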