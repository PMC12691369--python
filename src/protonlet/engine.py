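"""Plan-level accumulation: physical dose and dose-averaged LET.

Dose is the exact linear accumulation ``d(v) = sum_i w_i d_i(v)``.  The
dose-averaged LET pools all beams of the plan:

    LET_d(v) = sum_i w_i d_i(v) L_i(v) / sum_i w_i d_i(v),

set to 0 wherever the accumulated dose falls below a floor (default
1e-4 Gy) so that high-LET/negligible-dose voxels do not masquerade as
hotspots.  LET_d is invariant to a global rescaling of the weights and
lies within the [min, max] envelope of the contributing spot LETs.
"""

from __future__ import annotations

import numpy as np

from .core import DoseGrid, FractionationScheme, LETGrid
from .influence import InfluenceData

__all__ = ["accumulate_dose", "dose_averaged_let", "dose_and_let"]

DEFAULT_DOSE_FLOOR = 1e-4  # Gy


def _check_weights(influence: InfluenceData, weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (influence.n_spots,):
        raise ValueError(
            f"expected {influence.n_spots} weights, got shape {w.shape}"
        )
    if np.any(w < 0):
        raise ValueError("spot weights must be nonnegative")
    return w


def accumulate_dose(
    influence: InfluenceData,
    weights: np.ndarray,
    fractionation: FractionationScheme | None = None,
) -> DoseGrid:
    """Total physical dose grid for a spot-weight vector."""
    w = _check_weights(influence, weights)
    values = np.asarray(influence.dose.T @ w).reshape(influence.grid.shape)
    return DoseGrid(values=values, grid=influence.grid, fractionation=fractionation)


def dose_averaged_let(
    influence: InfluenceData,
    weights: np.ndarray,
    dose_floor: float = DEFAULT_DOSE_FLOOR,
) -> LETGrid:
    """Dose-averaged LET grid; 0 below the dose floor, never NaN."""
    if dose_floor < 0:
        raise ValueError("dose_floor must be >= 0")
    w = _check_weights(influence, weights)
    den = np.asarray(influence.dose.T @ w)
    num = np.asarray(influence.dose_let_product().T @ w)
    floor = max(dose_floor, np.finfo(float).tiny)
    values = np.where(den >= floor, num / np.where(den >= floor, den, 1.0), 0.0)
    return LETGrid(values=values.reshape(influence.grid.shape), grid=influence.grid)


def dose_and_let(
    influence: InfluenceData,
    weights: np.ndarray,
    fractionation: FractionationScheme | None = None,
    dose_floor: float = DEFAULT_DOSE_FLOOR,
) -> tuple[DoseGrid, LETGrid]:
    """Convenience: dose and LET_d grids for the same weights."""
    return (
        accumulate_dose(influence, weights, fractionation),
        dose_averaged_let(influence, weights, dose_floor),
    )
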