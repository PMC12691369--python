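"""Plan evaluation: maximum dose, RBE enhancement, DVHs, line profiles,
coverage checks and cohort summaries.

The RBE-enhancement metric for a structure is the ratio of the maximum
RBE-model dose over the structure to the maximum constant-RBE(1.1)
dose over the same structure.  The two maxima are taken independently
and may occur at different voxels; the maximum is the plain voxelwise
maximum (no small-volume surrogate), with a percentile alternative for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DoseGrid, LETGrid, VoxelGrid
from .rbe import RBEResult

__all__ = [
    "EnhancementRecord",
    "DVHCurve",
    "max_dose",
    "rbe_enhancement",
    "dvh",
    "line_profile",
    "coverage_check",
    "cohort_summary",
    "per_case_table",
    "selection_filter",
]

DELIVERY_MODES = ("pbs", "arc", "pbs_let_opt")


@dataclass(frozen=True)
class EnhancementRecord:
    structure: str
    model: str
    mode: str
    dmax_rbe11: float
    dmax_model: float
    enhancement: float
    case: str = ""

    def __post_init__(self) -> None:
        if self.enhancement <= 0:
            raise ValueError("enhancement must be > 0")


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of the structure at or
    above each dose edge.  Starts at 1 for 0 Gy and is non-increasing."""

    dose_edges: np.ndarray
    volume_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_gy": self.dose_edges, "volume_fraction": self.volume_fraction}
        )


def _mask_values(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape does not match grid shape")
    if not mask.any():
        raise ValueError("mask is empty")
    return values[mask]


def max_dose(dose: DoseGrid | np.ndarray, mask: np.ndarray, percentile: float | None = None) -> float:
    """Maximum (or percentile) dose over a structure mask (Gy)."""
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    sel = _mask_values(values, mask)
    if percentile is not None:
        return float(np.percentile(sel, percentile))
    return float(sel.max())


def rbe_enhancement(
    result: RBEResult,
    mask: np.ndarray,
    structure: str = "",
    mode: str = "pbs",
    case: str = "",
) -> EnhancementRecord:
    """RBE enhancement of a structure: max model dose / max 1.1 dose."""
    dmax_model = max_dose(result.rbe_model_dose, mask)
    dmax_11 = max_dose(result.rbe11_dose, mask)
    if dmax_11 <= 0:
        raise ValueError("maximum RBE 1.1 dose over the mask is zero")
    return EnhancementRecord(
        structure=structure,
        model=result.model,
        mode=mode,
        dmax_rbe11=dmax_11,
        dmax_model=dmax_model,
        enhancement=dmax_model / dmax_11,
        case=case,
    )


def dvh(dose: DoseGrid | np.ndarray, mask: np.ndarray, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH with the given dose bin width (Gy)."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    values = dose.values if isinstance(dose, DoseGrid) else np.asarray(dose)
    sel = _mask_values(values, mask)
    top = float(sel.max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    frac = np.array([(sel >= e).mean() for e in edges])
    return DVHCurve(dose_edges=edges, volume_fraction=frac)


def line_profile(
    grids: dict[str, DoseGrid | LETGrid | np.ndarray],
    grid: VoxelGrid,
    start_mm: tuple[float, float, float],
    end_mm: tuple[float, float, float],
    step_mm: float = 1.0,
) -> pd.DataFrame:
    """Trilinear samples of one or more grids along a segment.

    Returns a distance-indexed table with one column per named grid.
    A zero-length segment yields a single sample.  Raises if either
    endpoint lies outside the grid.
    """
    start = np.asarray(start_mm, float)
    end = np.asarray(end_mm, float)
    lo, hi = grid.bounds()
    for pt, label in ((start, "start"), (end, "end")):
        for ax in range(3):
            if grid.shape[ax] == 1:
                continue
            if pt[ax] < lo[ax] - 1e-9 or pt[ax] > hi[ax] + 1e-9:
                raise ValueError(f"{label} point lies outside the grid")
    length = float(np.linalg.norm(end - start))
    n = max(int(np.floor(length / step_mm)) + 1, 1)
    ts = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    pts = start[None, :] + ts[:, None] * (end - start)[None, :]
    # Continuous voxel-index coordinates (centre of voxel i at index i).
    coords = [
        (pts[:, ax] - grid.origin[ax]) / grid.voxel_size[ax] - 0.5 for ax in range(3)
    ]
    coords = [np.clip(c, 0, grid.shape[ax] - 1) for ax, c in enumerate(coords)]
    out = {"distance_mm": ts * length}
    for name, g in grids.items():
        values = g.values if hasattr(g, "values") else np.asarray(g)
        out[name] = ndimage.map_coordinates(
            values, np.vstack(coords), order=1, mode="nearest"
        )
    return pd.DataFrame(out)


def coverage_check(
    candidate: DoseGrid,
    reference: DoseGrid,
    targets: list,
    fractionation=None,
    tolerance: float = 0.001,
) -> dict[str, bool]:
    """Per-target check that V95 is preserved to within tolerance.

    V95 is the fraction of the target receiving at least 95% of its
    total prescription; the candidate passes if its V95 is no more than
    ``tolerance`` below the reference's.
    """
    frac = fractionation or candidate.fractionation or reference.fractionation
    results: dict[str, bool] = {}
    for t in targets:
        if t.prescription_per_fraction is None:
            raise ValueError(f"target {t.name!r} has no prescription")
        if frac is None:
            raise ValueError("no fractionation available for the coverage check")
        level = 0.95 * t.prescription_per_fraction * frac.n_fractions
        v95_cand = float((candidate.values[t.mask] >= level).mean())
        v95_ref = float((reference.values[t.mask] >= level).mean())
        results[t.name] = v95_cand >= v95_ref - tolerance
    return results


def cohort_summary(records: list[EnhancementRecord] | pd.DataFrame) -> pd.DataFrame:
    """Mean RBE enhancement grouped by (model, structure, delivery mode)."""
    df = _records_frame(records)
    out = (
        df.groupby(["model", "structure", "mode"], sort=True)
        .agg(mean_enhancement=("enhancement", "mean"), n=("enhancement", "size"))
        .reset_index()
    )
    return out


def per_case_table(records: list[EnhancementRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-case long table: one row per (case, structure, model, mode)
    with the paired maximum doses — the per-patient comparison view."""
    df = _records_frame(records)
    cols = ["case", "structure", "model", "mode", "dmax_rbe11", "dmax_model", "enhancement"]
    return df[cols].sort_values(cols[:4]).reset_index(drop=True)


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        if len(records) == 0:
            raise ValueError("no enhancement records")
        df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise ValueError("no enhancement records")
    return df


def selection_filter(cases: list, threshold: float = 50.0) -> list:
    """Retain cases whose listed OAR maximum physical dose reaches the
    threshold (default 50 Gy, inclusive).

    Each case must expose ``oar_max_physical_dose`` — either a scalar or
    a mapping of structure name to Gy; the case is retained if any value
    is >= threshold.
    """
    kept = []
    for c in cases:
        dmax = getattr(c, "oar_max_physical_dose", None)
        if dmax is None:
            raise ValueError("case lacks oar_max_physical_dose")
        values = dmax.values() if isinstance(dmax, dict) else [dmax]
        if any(v >= threshold for v in values):
            kept.append(c)
    return kept
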