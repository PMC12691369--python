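"""Variable proton RBE models: McMahon (linear in LET_d) and McNamara
(phenomenological, linear-quadratic based), plus the constant-1.1
clinical reference.

McMahon:

    RBE = 1 + kappa * LET_d,          kappa = 0.055 µm/keV.

McNamara (per fraction, LQ-derived):

    RBE(D_p, LET_d, (a/b)_x) =
        1 / (2 D_p) * ( sqrt( (a/b)_x^2 + 4 D_p (a/b)_x RBE_max
                              + 4 D_p^2 RBE_min^2 ) - (a/b)_x )

with the asymptotes (D_p -> 0 and D_p -> inf)

    RBE_max = 0.99064 + 0.35605 * LET_d / (a/b)_x
    RBE_min = 1.1012  - 0.0038703 * sqrt((a/b)_x) * LET_d.

``(a/b)_x`` is the photon-data alpha/beta ratio: 2.5 Gy for
late-responding nervous tissue, 10 Gy for tumour by default.  The
published coefficient table is occasionally rendered with the alpha/beta
dependence typographically flattened; this module uses the original
McNamara functional forms above, which coincide with any reading at
(a/b)_x = 1 Gy.  RBE_min can turn negative at extreme LET; it is floored
(default at 0) with a warning, since a negative RBE is unphysical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_ALPHA_BETA, DoseGrid, LETGrid, Phantom, Role

__all__ = [
    "RBEModelParams",
    "rbe_mcmahon",
    "rbe_max",
    "rbe_min",
    "rbe_mcnamara",
    "assign_tissue_map",
    "RBEResult",
    "compute_rbe_dose",
    "MODELS",
]

MODELS = ("mcmahon", "mcnamara")


@dataclass(frozen=True)
class RBEModelParams:
    """Published model coefficients; override only deliberately."""

    kappa: float = 0.055  # µm/keV (McMahon slope)
    c0_max: float = 0.99064
    c1_max: float = 0.35605
    c0_min: float = 1.1012
    c1_min: float = 0.0038703
    constant_rbe: float = 1.1
    rbe_min_floor: float = 0.0
    dp_threshold: float = 1e-6  # Gy; below this, return the D_p -> 0 limit

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


DEFAULT_PARAMS = RBEModelParams()


def _check_let(let_d: np.ndarray | float) -> np.ndarray:
    arr = np.asarray(let_d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("LET_d must be >= 0")
    return arr


def _check_ab(alpha_beta: np.ndarray | float) -> np.ndarray:
    ab = np.asarray(alpha_beta, dtype=float)
    if np.any(ab <= 0):
        raise ValueError("alpha/beta must be > 0")
    return ab


def rbe_mcmahon(
    let_d: np.ndarray | float, params: RBEModelParams = DEFAULT_PARAMS
) -> np.ndarray | float:
    """Linear LET-weighted RBE: 1 + kappa * LET_d."""
    arr = _check_let(let_d)
    out = 1.0 + params.kappa * arr
    return out if out.shape else float(out)


def rbe_max(
    let_d: np.ndarray | float,
    alpha_beta: np.ndarray | float,
    params: RBEModelParams = DEFAULT_PARAMS,
) -> np.ndarray | float:
    """McNamara low-dose asymptote RBE_max."""
    arr = _check_let(let_d)
    ab = _check_ab(alpha_beta)
    out = params.c0_max + params.c1_max * arr / ab
    return out if out.shape else float(out)


def rbe_min(
    let_d: np.ndarray | float,
    alpha_beta: np.ndarray | float,
    params: RBEModelParams = DEFAULT_PARAMS,
) -> np.ndarray | float:
    """McNamara high-dose asymptote RBE_min, floored if negative."""
    arr = _check_let(let_d)
    ab = _check_ab(alpha_beta)
    out = params.c0_min - params.c1_min * np.sqrt(ab) * arr
    if np.any(out < params.rbe_min_floor):
        warnings.warn(
            "RBE_min linear form went below its floor "
            f"({params.rbe_min_floor}); clamping",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.maximum(out, params.rbe_min_floor)
    return out if out.shape else float(out)


def rbe_mcnamara(
    dose_per_fraction: np.ndarray | float,
    let_d: np.ndarray | float,
    alpha_beta: np.ndarray | float,
    params: RBEModelParams = DEFAULT_PARAMS,
) -> np.ndarray | float:
    """McNamara RBE at physical proton dose per fraction D_p.

    Below ``params.dp_threshold`` the analytic D_p -> 0 limit (RBE_max)
    is returned to avoid the 0/0 form.
    """
    dp = np.asarray(dose_per_fraction, dtype=float)
    if np.any(dp < 0):
        raise ValueError("dose per fraction must be >= 0")
    arr = _check_let(let_d)
    ab = _check_ab(alpha_beta)
    rmax = np.asarray(rbe_max(arr, ab, params))
    rmin = np.asarray(rbe_min(arr, ab, params))
    dp_safe = np.where(dp < params.dp_threshold, 1.0, dp)
    root = np.sqrt(ab**2 + 4.0 * dp_safe * ab * rmax + 4.0 * dp_safe**2 * rmin**2)
    full = (root - ab) / (2.0 * dp_safe)
    out = np.where(dp < params.dp_threshold, rmax, full)
    return out if out.shape else float(out)


def assign_tissue_map(
    phantom: Phantom, default_alpha_beta: float = 2.5
) -> np.ndarray:
    """Per-voxel alpha/beta map (Gy).

    Targets get their structure alpha/beta (default 10 Gy), nervous OARs
    2.5 Gy; where a target and an OAR overlap, the OAR value wins (the
    conservative, late-responding assignment).  Unlabelled voxels get
    ``default_alpha_beta``.
    """
    ab = np.full(phantom.grid.shape, float(default_alpha_beta))
    for s in phantom.structures:
        if s.role.is_target:
            ab[s.mask] = s.alpha_beta
    for s in phantom.structures:
        if s.role.is_oar:
            ab[s.mask] = s.alpha_beta
    return ab


@dataclass
class RBEResult:
    """Per-voxel RBE and RBE-weighted dose grids for one model."""

    model: str
    rbe: np.ndarray
    rbe_model_dose: DoseGrid
    rbe11_dose: DoseGrid
    params: RBEModelParams = DEFAULT_PARAMS


def compute_rbe_dose(
    dose: DoseGrid,
    let: LETGrid,
    tissue: np.ndarray,
    model: str,
    params: RBEModelParams = DEFAULT_PARAMS,
) -> RBEResult:
    """RBE-weighted total dose under one model, plus the 1.1 reference.

    McMahon RBE is dose-independent; McNamara is evaluated at the
    per-fraction dose ``total / n_fractions`` (uniform fractionation)
    and the RBE-weighted total is ``n_fractions * RBE * D_p``, i.e.
    ``RBE * total`` voxelwise.
    """
    model = model.lower()
    if model not in MODELS:
        raise ValueError(f"unknown RBE model {model!r}; expected one of {MODELS}")
    tissue = np.asarray(tissue, dtype=float)
    if tuple(tissue.shape) != dose.grid.shape or dose.values.shape != let.values.shape:
        raise ValueError("dose, LET and tissue grids are not congruent")

    if model == "mcmahon":
        rbe = np.asarray(rbe_mcmahon(let.values, params))
    else:
        dp = dose.per_fraction()
        rbe = np.asarray(rbe_mcnamara(dp, let.values, tissue, params))

    model_dose = DoseGrid(
        values=rbe * dose.values, grid=dose.grid, fractionation=dose.fractionation
    )
    rbe11 = DoseGrid(
        values=params.constant_rbe * dose.values,
        grid=dose.grid,
        fractionation=dose.fractionation,
    )
    return RBEResult(
        model=model, rbe=rbe, rbe_model_dose=model_dose, rbe11_dose=rbe11, params=params
    )
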