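"""Spot-weight inverse planning with quadratic dose objectives and a
dose-weighted LET-excess objective.

Dose objectives are the usual voxelwise quadratic penalties (uniform /
max-dose / min-dose), each normalised by its structure's voxel count so
weights are comparable across structure sizes.  The LET objective
realises the "cap above a dose threshold" strategy: in an outer loop,
voxels of each LET-objective structure whose current dose is at or
above ``dose_threshold_fraction`` of the structure's desired maximum
dose are flagged, and a convex surrogate penalty

    sum_{v flagged} max(0, sum_i w_i d_i(v) (L_i(v) - cap))^2

(i.e. the squared positive part of dose(v) * (LET_d(v) - cap)) is added
and the weights re-solved by projected gradient.  Contributions below
the cap offset contributions above it inside the hinge, so the
optimizer can trade high-LET for low-LET coverage routes, not just cut
dose.  The outer loop runs a fixed number of passes (default 5) for
reproducibility; LET_d depends on weight ratios and is not monotone
under reweighting, so a convergence test on it would be fragile.

The inner solver is projected gradient (nonnegativity projection) with
Armijo backtracking on the quadratic model, deterministic given the
inputs and the initialisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import sparse

from .core import Phantom, Role
from .engine import DEFAULT_DOSE_FLOOR, accumulate_dose, dose_averaged_let
from .influence import InfluenceData

__all__ = [
    "DoseObjective",
    "LETObjective",
    "OptimizationResult",
    "optimize_dose",
    "optimize_with_let",
    "strategy_grid_search",
    "default_objective_template",
]

log = logging.getLogger(__name__)

GLOBAL_THRESHOLD = "global"


@dataclass(frozen=True)
class DoseObjective:
    structure: str
    kind: str  # uniform | max_dose | min_dose
    level: float  # Gy, total course dose
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "max_dose", "min_dose"):
            raise ValueError(f"unknown dose objective kind {self.kind!r}")
        if self.level < 0 or self.weight < 0:
            raise ValueError("objective level and weight must be >= 0")


@dataclass(frozen=True)
class LETObjective:
    """Cap LET_d in a structure above a dose threshold.

    ``dose_threshold_fraction`` is a fraction of the structure's desired
    maximum dose (the clinical-goal reading of "80% maximum dose
    threshold"), or the sentinel ``"global"`` to flag every voxel with
    more than the evaluation dose floor.
    """

    structure: str
    let_cap: float = 2.5  # keV/µm
    dose_threshold_fraction: float | str = 0.8
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.let_cap <= 0:
            raise ValueError("let_cap must be > 0")
        f = self.dose_threshold_fraction
        if f != GLOBAL_THRESHOLD and not (0.0 <= float(f) <= 1.0):
            raise ValueError(
                "dose_threshold_fraction must be in [0, 1] or 'global'"
            )
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


@dataclass
class OptimizationResult:
    weights: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iterations: int = 0
    flagged_counts: list[dict[str, int]] = field(default_factory=list)
    let_report: dict = field(default_factory=dict)


def _build_dose_objective_eval(
    influence: InfluenceData,
    phantom: Phantom,
    objectives: list[DoseObjective],
) -> tuple[Callable[[np.ndarray], float], Callable[[np.ndarray, np.ndarray], np.ndarray]]:
    """Closures (f over full dose vector, residual gradient assembler)."""
    terms = []
    for obj in objectives:
        idx = phantom.structure(obj.structure).flat_indices()
        terms.append((obj, idx, obj.weight / idx.size))

    def f_of_dose(d: np.ndarray) -> float:
        total = 0.0
        for obj, idx, scale in terms:
            dv = d[idx]
            if obj.kind == "uniform":
                r = dv - obj.level
            elif obj.kind == "max_dose":
                r = np.maximum(dv - obj.level, 0.0)
            else:
                r = np.minimum(dv - obj.level, 0.0)
            total += scale * float(r @ r)
        return total

    def residual_into(d: np.ndarray, out: np.ndarray) -> np.ndarray:
        """Accumulate d(f)/d(dose) into ``out`` (full voxel vector)."""
        for obj, idx, scale in terms:
            dv = d[idx]
            if obj.kind == "uniform":
                r = dv - obj.level
            elif obj.kind == "max_dose":
                r = np.maximum(dv - obj.level, 0.0)
            else:
                r = np.minimum(dv - obj.level, 0.0)
            np.add.at(out, idx, 2.0 * scale * r)
        return out

    return f_of_dose, residual_into


def _projected_gradient(
    influence: InfluenceData,
    f_of_dose: Callable[[np.ndarray], float],
    residual_into: Callable[[np.ndarray, np.ndarray], np.ndarray],
    w0: np.ndarray,
    penalties: list[tuple[sparse.csr_matrix, float]],
    max_iters: int,
    tol: float,
) -> tuple[np.ndarray, list[float], bool, int]:
    """Armijo projected gradient over nonnegative weights.

    ``penalties`` is a list of (B, scale): B maps weights to the signed
    dose-weighted LET excess on the flagged voxels; the penalty is
    scale * || max(0, B w) ||^2.
    """
    A = influence.dose  # (spots, voxels)
    w = np.maximum(np.asarray(w0, dtype=float), 0.0)

    def evaluate(wv: np.ndarray) -> tuple[float, np.ndarray]:
        d = np.asarray(A.T @ wv)
        val = f_of_dose(d)
        res = np.zeros_like(d)
        residual_into(d, res)
        grad = np.asarray(A @ res)
        for B, scale in penalties:
            e = np.maximum(np.asarray(B @ wv), 0.0)
            val += scale * float(e @ e)
            grad += 2.0 * scale * np.asarray(B.T @ e)
        return val, grad

    fw, gw = evaluate(w)
    trace = [fw]
    alpha = 1.0 / max(float(np.abs(gw).max()), 1e-12)
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        accepted = False
        for _ in range(40):
            w_new = np.maximum(w - alpha * gw, 0.0)
            step = w_new - w
            f_new, g_new = evaluate(w_new)
            # Armijo with the projected-step quadratic model.
            model = fw + float(gw @ step) + float(step @ step) / (2.0 * alpha)
            if f_new <= model + 1e-12 * max(abs(fw), 1.0):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        rel = abs(fw - f_new) / max(abs(fw), 1e-30)
        w, fw, gw = w_new, f_new, g_new
        trace.append(fw)
        alpha *= 1.3
        if rel < tol:
            converged = True
            break
    return w, trace, converged, it


def _initial_weights(
    influence: InfluenceData, phantom: Phantom, objectives: list[DoseObjective]
) -> np.ndarray:
    """Uniform weights scaled so the mean target dose matches the first
    uniform objective level (deterministic)."""
    target_objs = [o for o in objectives if o.kind == "uniform"]
    level = target_objs[0].level if target_objs else 1.0
    idx = phantom.structure(
        (target_objs[0] if target_objs else objectives[0]).structure
    ).flat_indices()
    ones = np.ones(influence.n_spots)
    d = np.asarray(influence.dose.T @ ones)
    mean = float(d[idx].mean())
    if mean <= 0:
        raise ValueError("influence is empty on the target (infeasible)")
    return ones * (level / mean)


def _has_target_objective(phantom: Phantom, objectives: list[DoseObjective]) -> bool:
    return any(
        phantom.structure(o.structure).role.is_target and o.kind in ("uniform", "min_dose")
        for o in objectives
    )


def optimize_dose(
    influence: InfluenceData,
    phantom: Phantom,
    objectives: list[DoseObjective],
    max_iters: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    w0: np.ndarray | None = None,
) -> OptimizationResult:
    """Dose-only spot-weight optimization by projected gradient.

    Deterministic given the inputs; ``seed`` is reserved for optional
    randomised initialisation and is unused with the default
    deterministic start.
    """
    if not _has_target_objective(phantom, objectives):
        raise ValueError("at least one target objective is required")
    if w0 is None:
        w0 = _initial_weights(influence, phantom, objectives)
    f_of_dose, residual_into = _build_dose_objective_eval(influence, phantom, objectives)
    w, trace, converged, n_it = _projected_gradient(
        influence, f_of_dose, residual_into, w0, [], max_iters, tol
    )
    return OptimizationResult(
        weights=w, objective_trace=trace, converged=converged, n_iterations=n_it
    )


def _let_penalty_matrices(
    influence: InfluenceData,
    phantom: Phantom,
    let_objectives: list[LETObjective],
    dose: np.ndarray,
    dose_floor: float,
) -> tuple[list[tuple[sparse.csr_matrix, np.ndarray, float, str]], dict[str, int]]:
    """Flag voxels and build the per-objective penalty operators."""
    penalties = []
    counts: dict[str, int] = {}
    csc_dose = influence.dose_csc()
    csc_let = influence.let.tocsc()
    for lo in let_objectives:
        struct = phantom.structure(lo.structure)
        idx = struct.flat_indices()
        if lo.dose_threshold_fraction == GLOBAL_THRESHOLD:
            thr = dose_floor
        else:
            if struct.desired_max_dose is None:
                raise ValueError(
                    f"structure {lo.structure!r} has no desired_max_dose for "
                    "the LET objective threshold"
                )
            thr = float(lo.dose_threshold_fraction) * struct.desired_max_dose
        flagged = idx[dose[idx] >= thr]
        counts[lo.structure] = int(flagged.size)
        if flagged.size == 0:
            continue
        Dsub = csc_dose[:, flagged]
        Lsub = csc_let[:, flagged]
        excess = Lsub.copy()
        excess.data = excess.data - lo.let_cap
        B = (Dsub.multiply(excess)).T.tocsr()  # (flagged, spots)
        scale = lo.weight / struct.n_voxels
        penalties.append((B, flagged, scale, lo.structure))
    return penalties, counts


def optimize_with_let(
    influence: InfluenceData,
    phantom: Phantom,
    dose_objectives: list[DoseObjective],
    let_objectives: list[LETObjective],
    outer_iters: int = 5,
    inner_max_iters: int = 200,
    tol: float = 1e-6,
    dose_floor: float = DEFAULT_DOSE_FLOOR,
    warm: OptimizationResult | None = None,
    seed: int = 0,
) -> OptimizationResult:
    """LET-capped re-optimization around a dose-only solution.

    Outer loop (fixed count): accumulate dose and LET_d at the current
    weights, flag above-threshold voxels per LET objective, add the
    convex dose-weighted LET-excess surrogate, and re-solve by projected
    gradient.  If no voxel is flagged on the first pass, a warning is
    issued and the dose-only solution is returned.  If every influence
    LET entry in the flagged structures is at or below the cap, the
    penalty is identically zero for nonnegative weights and the warm
    solution is returned unchanged (bitwise).
    """
    if warm is None:
        warm = optimize_dose(
            influence, phantom, dose_objectives, max_iters=500, tol=tol, seed=seed
        )
    w = warm.weights.copy()
    f_of_dose, residual_into = _build_dose_objective_eval(
        influence, phantom, dose_objectives
    )

    pre_let = dose_averaged_let(influence, warm.weights, dose_floor).values.ravel()
    pre_dose = np.asarray(influence.dose.T @ warm.weights)

    result = OptimizationResult(weights=w)
    flagged_union: dict[str, np.ndarray] = {}
    for outer in range(outer_iters):
        d = np.asarray(influence.dose.T @ w)
        penalties, counts = _let_penalty_matrices(
            influence, phantom, let_objectives, d, dose_floor
        )
        result.flagged_counts.append(counts)
        if outer == 0:
            if not penalties:
                warnings.warn(
                    "no voxels above the LET-objective dose threshold; "
                    "returning the dose-only solution",
                    RuntimeWarning,
                    stacklevel=2,
                )
                result.weights = warm.weights
                result.objective_trace = list(warm.objective_trace[-1:])
                result.converged = warm.converged
                return result
            for _B, flagged, _s, sname in penalties:
                flagged_union[sname] = flagged
        if penalties and all((B.data <= 0).all() for B, _i, _s, _n in penalties):
            # Inactive cap: the hinge penalty is zero for every w >= 0,
            # so the inner problem equals the dose-only problem already
            # solved; keep the warm iterate bitwise.
            log.info("LET cap inactive (all spot LET <= cap); skipping re-solve")
            result.weights = w
            dval = f_of_dose(np.asarray(influence.dose.T @ w))
            result.objective_trace.append(dval)
            result.converged = True
            continue
        w, trace, converged, n_it = _projected_gradient(
            influence,
            f_of_dose,
            residual_into,
            w,
            [(B, s) for B, _i, s, _n in penalties],
            inner_max_iters,
            tol,
        )
        result.n_iterations += n_it
        result.converged = converged
        result.objective_trace.append(trace[-1])
        log.info(
            "LET outer pass %d: flagged=%s, objective=%.6g, inner iters=%d",
            outer + 1,
            counts,
            trace[-1],
            n_it,
        )

    result.weights = w
    post_let = dose_averaged_let(influence, w, dose_floor).values.ravel()
    post_dose = np.asarray(influence.dose.T @ w)
    report = {}
    for name, flagged in flagged_union.items():
        report[name] = {
            "pre_max_let": float(pre_let[flagged].max()) if flagged.size else 0.0,
            "post_max_let": float(post_let[flagged].max()) if flagged.size else 0.0,
            "pre_mean_let": float(pre_let[flagged].mean()) if flagged.size else 0.0,
            "post_mean_let": float(post_let[flagged].mean()) if flagged.size else 0.0,
            "pre_max_dose": float(pre_dose[flagged].max()) if flagged.size else 0.0,
            "post_max_dose": float(post_dose[flagged].max()) if flagged.size else 0.0,
        }
    result.let_report = report
    return result


def default_objective_template(
    phantom: Phantom,
    prescription_total: float,
    target_weight: float = 100.0,
    oar_weight: float = 20.0,
    oar_level_fraction: float = 0.9,
    external_weight: float = 1.0,
) -> list[DoseObjective]:
    """The OAR + target objective template used for every plan arm."""
    objs: list[DoseObjective] = []
    for s in phantom.targets:
        objs.append(
            DoseObjective(s.name, "uniform", prescription_total, target_weight)
        )
    for s in phantom.oars:
        level = oar_level_fraction * (s.desired_max_dose or prescription_total)
        objs.append(DoseObjective(s.name, "max_dose", level, oar_weight))
    objs.append(
        DoseObjective(
            phantom.external().name, "max_dose", 1.05 * prescription_total, external_weight
        )
    )
    return objs


def strategy_grid_search(
    influence: InfluenceData,
    phantom: Phantom,
    dose_objectives: list[DoseObjective],
    let_structures: list[str],
    prescription_total: float,
    fractionation=None,
    caps: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0),
    thresholds: tuple = (GLOBAL_THRESHOLD, 0.5, 0.8, 0.9),
    let_weight: float = 1.0,
    outer_iters: int = 5,
    dose_floor: float = DEFAULT_DOSE_FLOOR,
    eval_dose_fraction: float = 0.5,
) -> pd.DataFrame:
    """Screen LET_d caps x dose thresholds, one re-optimization each.

    For every (cap, threshold) pair the PBS plan is re-optimized with
    that LET objective on each named structure, and the table records
    target coverage (V95), per-structure maximum LET_d change and the
    maximum RBE-weighted dose / RBE enhancement under both models.  The
    LET_d change is evaluated over a fixed region — structure voxels at
    or above ``eval_dose_fraction`` of the desired maximum dose in the
    dose-only plan — so rows are comparable.  Rows are ranked: coverage
    preserved first, then mean enhancement.
    """
    from .analysis import rbe_enhancement  # local import to avoid a cycle
    from .core import FractionationScheme
    from .rbe import assign_tissue_map, compute_rbe_dose

    if fractionation is None:
        fractionation = FractionationScheme()
    base = optimize_dose(influence, phantom, dose_objectives)
    base_dose = accumulate_dose(influence, base.weights, fractionation)
    base_let = dose_averaged_let(influence, base.weights, dose_floor)
    tissue = assign_tissue_map(phantom)

    target = phantom.targets[0]
    t_idx = target.flat_indices()
    v95_level = 0.95 * prescription_total

    def v95(dose_vals: np.ndarray) -> float:
        return float(np.mean(dose_vals.ravel()[t_idx] >= v95_level))

    def d95(dose_vals: np.ndarray) -> float:
        # Continuous coverage companion to V95: dose covering 95% of
        # the target (5th percentile).
        return float(np.percentile(dose_vals.ravel()[t_idx], 5))

    base_v95 = v95(base_dose.values)
    base_d95 = d95(base_dose.values)

    eval_regions = {}
    for name in let_structures:
        s = phantom.structure(name)
        idx = s.flat_indices()
        thr = eval_dose_fraction * (s.desired_max_dose or prescription_total)
        region = idx[base_dose.values.ravel()[idx] >= thr]
        eval_regions[name] = region if region.size else idx
    base_max_let = {
        name: float(base_let.values.ravel()[idx].max())
        for name, idx in eval_regions.items()
    }

    rows = []
    for cap in caps:
        for thr in thresholds:
            lobjs = [
                LETObjective(name, let_cap=cap, dose_threshold_fraction=thr, weight=let_weight)
                for name in let_structures
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = optimize_with_let(
                    influence,
                    phantom,
                    dose_objectives,
                    lobjs,
                    outer_iters=outer_iters,
                    warm=base,
                    dose_floor=dose_floor,
                )
            dgrid = accumulate_dose(influence, res.weights, fractionation)
            lgrid = dose_averaged_let(influence, res.weights, dose_floor)
            row = {
                "let_cap": cap,
                "dose_threshold": thr,
                "target_v95": v95(dgrid.values),
                "target_d95": d95(dgrid.values),
                "coverage_change": v95(dgrid.values) - base_v95,
                "d95_change": d95(dgrid.values) - base_d95,
            }
            results_by_model = {
                model: compute_rbe_dose(dgrid, lgrid, tissue, model)
                for model in ("mcmahon", "mcnamara")
            }
            enh_vals = []
            for name in let_structures:
                region = eval_regions[name]
                max_let = float(lgrid.values.ravel()[region].max())
                row[f"{name}_max_let"] = max_let
                row[f"{name}_let_change"] = max_let - base_max_let[name]
                mask = phantom.structure(name).mask
                for model, rr in results_by_model.items():
                    rec = rbe_enhancement(rr, mask, structure=name, mode="pbs_let_opt")
                    row[f"{name}_dmax_{model}"] = rec.dmax_model
                    row[f"{name}_enhancement_{model}"] = rec.enhancement
                    enh_vals.append(rec.enhancement)
            row["mean_enhancement"] = float(np.mean(enh_vals))
            rows.append(row)
    table = pd.DataFrame(rows)
    table["coverage_ok"] = table["target_v95"] >= base_v95 - 1e-3
    table = table.sort_values(
        ["coverage_ok", "mean_enhancement"], ascending=[False, True]
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
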