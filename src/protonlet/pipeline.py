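"""End-to-end synthetic study: case specs, cohort generation, and the
three-arm (PBS / arc / LET-optimized PBS) x two-model (McMahon /
McNamara) factorial evaluation.

A case is a water phantom with one target and two nervous-tissue OARs:
a brainstem/chiasm analogue at the distal edge of the reference beam
and an optic-nerve analogue in the entrance region.  The bilateral
arrangement uses three static beams — one anterior-posterior beam
(gantry 0) whose distal edge abuts the posterior-midline OAR, plus two
posterior obliques (150/210) that reach the same target voxels through
low-LET entrance paths — and two mirrored 130 degree arcs (30-160 with
a 180 degree couch kick), whose anterior-oblique sectors share distal
edges in the OAR; the unilateral arrangement uses an anterior and a
posterior oblique (45/135) and a single arc on the target side.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (
    EnhancementRecord,
    cohort_summary,
    per_case_table,
    rbe_enhancement,
)
from .beams import make_arc_beams, make_pbs_beams, make_spots
from .core import FractionationScheme, Phantom, Role
from .engine import DEFAULT_DOSE_FLOOR, accumulate_dose, dose_averaged_let
from .influence import compute_influence
from .optimize import (
    LETObjective,
    OptimizationResult,
    default_objective_template,
    optimize_dose,
    optimize_with_let,
)
from .phantom import OARSpec, PhantomConfig, TargetSpec, build_phantom
from .rbe import assign_tissue_map, compute_rbe_dose

__all__ = [
    "CaseSpec",
    "CaseResult",
    "canonical_case",
    "generate_cohort",
    "build_case",
    "run_case",
    "run_cohort",
    "ARMS",
]

log = logging.getLogger(__name__)

ARMS = ("pbs", "arc", "pbs_let_opt")

_ROLE_PRESCRIPTION = {
    Role.TARGET_HIGH: 2.0,
    Role.TARGET_INTERMEDIATE: 1.8,
    Role.TARGET_STANDARD: 1.6,
}


@dataclass(frozen=True)
class CaseSpec:
    """Declarative description of one synthetic case."""

    name: str = "case"
    seed: int = 0
    grid_shape: tuple[int, int, int] = (60, 60, 1)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    target_size_mm: float = 20.0
    target_role: str = Role.TARGET_HIGH.value
    n_fractions: int = 33
    distal_gap_mm: float = 2.0
    entrance_gap_mm: float = 14.0
    oar_size_mm: float = 12.0
    entrance_oar_placement: str = "entrance"
    desired_max_dose: float = 60.0
    arrangement: str = "bilateral_3beam"  # or unilateral_2beam
    arc_span: float = 130.0
    arc_start: float = 30.0
    arc_step: float = 5.0
    pbs_layer_scale: float = 1.0
    arc_layer_scale: float = 0.25
    pbs_spot_scale: float = 0.7
    arc_spot_spacing_mm: float = 6.0
    arc_lateral_margin_mm: float = 5.0
    let_cap: float = 2.5
    let_dose_threshold: float | str = 0.8
    let_weight: float = 3.0
    let_outer_iters: int = 5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown case config fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "voxel_size"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def canonical_case(seed: int = 1234) -> CaseSpec:
    """The canonical distal-edge case used throughout the tests: a
    high-risk 66 Gy / 33 fx target abutting the distal OAR by 2 mm."""
    return CaseSpec(name="canonical_distal_edge", seed=seed)


def generate_cohort(
    n_cases: int = 15,
    seed: int = 0,
    variation: dict | None = None,
) -> list[CaseSpec]:
    """Seeded cohort of cases varying target-OAR gap (1-10 mm), the
    second OAR's placement, prescription tier/fractions and beam
    arrangement.  Reproducible: the same (n_cases, seed, variation)
    yields identical specs."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    variation = dict(variation or {})
    gaps = tuple(variation.get("gap_range_mm", (1.0, 10.0)))
    roles = tuple(variation.get("target_roles", [r.value for r in _ROLE_PRESCRIPTION]))
    fractions = tuple(variation.get("n_fractions", (33, 35)))
    arrangements = tuple(
        variation.get("arrangements", ("bilateral_3beam", "unilateral_2beam"))
    )
    placements = tuple(variation.get("entrance_placements", ("entrance", "lateral")))
    overrides = dict(variation.get("overrides", {}))

    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_cases):
        spec = CaseSpec(
            name=f"case_{i:03d}",
            seed=int(rng.integers(0, 2**31 - 1)),
            distal_gap_mm=float(np.round(rng.uniform(*gaps), 1)),
            target_role=str(rng.choice(roles)),
            n_fractions=int(rng.choice(fractions)),
            arrangement=str(rng.choice(arrangements)),
            entrance_oar_placement=str(rng.choice(placements)),
            **overrides,
        )
        specs.append(spec)
    return specs


def _arrangement(spec: CaseSpec) -> tuple[list[float], float, bool]:
    """(static gantry angles, reference angle for OAR placement,
    bilateral arc flag)."""
    if spec.arrangement == "bilateral_3beam":
        return [0.0, 150.0, 210.0], 0.0, True
    if spec.arrangement == "unilateral_2beam":
        # OAR placed along the arc's central axis (medial to the target),
        # where the two obliques' distal edges converge.
        return [45.0, 135.0], 90.0, False
    raise ValueError(f"unknown arrangement {spec.arrangement!r}")


def build_case(spec: CaseSpec) -> tuple[Phantom, list, list]:
    """Phantom plus populated PBS and arc beams for a case spec."""
    angles, ref_angle, bilateral = _arrangement(spec)
    role = Role(spec.target_role)
    config = PhantomConfig(
        grid_shape=spec.grid_shape,
        voxel_size=spec.voxel_size,
        targets=(
            TargetSpec(
                name="target",
                role=role,
                size_mm=(spec.target_size_mm,) * 3,
                prescription_per_fraction=_ROLE_PRESCRIPTION[role],
            ),
        ),
        oars=(
            OARSpec(
                name="brainstem",
                placement="distal_edge",
                gap_mm=spec.distal_gap_mm,
                size_mm=(spec.oar_size_mm,) * 3,
                desired_max_dose=spec.desired_max_dose,
            ),
            OARSpec(
                name="optic_nerve",
                placement=spec.entrance_oar_placement,
                gap_mm=spec.entrance_gap_mm,
                size_mm=(spec.oar_size_mm,) * 3,
                desired_max_dose=spec.desired_max_dose,
            ),
        ),
        reference_gantry_angle=ref_angle,
    )
    phantom = build_phantom(config)
    pbs_beams = make_pbs_beams(
        phantom, angles, layer_scale=spec.pbs_layer_scale, spot_scale=spec.pbs_spot_scale
    )
    arc_beams = [
        make_spots(
            phantom,
            b,
            layer_scale=spec.arc_layer_scale,
            spot_spacing=spec.arc_spot_spacing_mm,
            lateral_margin=spec.arc_lateral_margin_mm,
        )
        for b in make_arc_beams(
            spec.arc_span, spec.arc_start, spec.arc_step, bilateral=bilateral
        )
    ]
    return phantom, pbs_beams, arc_beams


@dataclass
class CaseResult:
    spec: CaseSpec
    records: list[EnhancementRecord] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    oar_max_physical_dose: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    optimization: dict = field(default_factory=dict)

    @property
    def included(self) -> bool:
        """Cohort inclusion: any nervous OAR with Dmax >= 50 Gy (PBS)."""
        return any(v >= 50.0 for v in self.oar_max_physical_dose.values())


def run_case(
    spec: CaseSpec,
    arms: tuple[str, ...] = ARMS,
    keep_grids: bool = False,
    dose_floor: float = DEFAULT_DOSE_FLOOR,
) -> CaseResult:
    """Plan and evaluate one case across the requested delivery arms."""
    phantom, pbs_beams, arc_beams = build_case(spec)
    frac = FractionationScheme(spec.n_fractions)
    role = Role(spec.target_role)
    prescription_total = frac.total_dose(role)
    objectives = default_objective_template(phantom, prescription_total)
    tissue = assign_tissue_map(phantom)
    target = phantom.structure("target")
    v95_level = 0.95 * prescription_total

    result = CaseResult(spec=spec)
    influences: dict[str, object] = {}
    solutions: dict[str, OptimizationResult] = {}

    infl_pbs = compute_influence(phantom, pbs_beams)
    influences["pbs"] = infl_pbs
    sol_pbs = optimize_dose(infl_pbs, phantom, objectives, seed=spec.seed)
    solutions["pbs"] = sol_pbs

    if "arc" in arms:
        infl_arc = compute_influence(phantom, arc_beams)
        influences["arc"] = infl_arc
        solutions["arc"] = optimize_dose(infl_arc, phantom, objectives, seed=spec.seed)
    if "pbs_let_opt" in arms:
        influences["pbs_let_opt"] = infl_pbs
        lobjs = [
            LETObjective(
                s.name,
                let_cap=spec.let_cap,
                dose_threshold_fraction=spec.let_dose_threshold,
                weight=spec.let_weight,
            )
            for s in phantom.oars
            if s.role is Role.OAR_NERVOUS
        ]
        solutions["pbs_let_opt"] = optimize_with_let(
            infl_pbs,
            phantom,
            objectives,
            lobjs,
            outer_iters=spec.let_outer_iters,
            warm=sol_pbs,
            dose_floor=dose_floor,
            seed=spec.seed,
        )
        result.optimization["let_report"] = solutions["pbs_let_opt"].let_report
        result.optimization["flagged_counts"] = solutions["pbs_let_opt"].flagged_counts

    for arm in arms:
        if arm not in solutions:
            continue
        infl = influences[arm]
        w = solutions[arm].weights
        dose = accumulate_dose(infl, w, frac)
        let = dose_averaged_let(infl, w, dose_floor)
        result.metrics[f"{arm}_v95"] = float(
            (dose.values[target.mask] >= v95_level).mean()
        )
        for oar in phantom.oars:
            result.metrics[f"{arm}_{oar.name}_dmax_physical"] = float(
                dose.values[oar.mask].max()
            )
            result.metrics[f"{arm}_{oar.name}_max_let"] = float(
                let.values[oar.mask].max()
            )
        if arm == "pbs":
            for oar in phantom.oars:
                result.oar_max_physical_dose[oar.name] = float(
                    dose.values[oar.mask].max()
                )
        for model in ("mcmahon", "mcnamara"):
            rr = compute_rbe_dose(dose, let, tissue, model)
            for oar in phantom.oars:
                result.records.append(
                    rbe_enhancement(rr, oar.mask, structure=oar.name, mode=arm, case=spec.name)
                )
        if keep_grids:
            result.grids[arm] = {"dose": dose, "let": let}
            result.weights[arm] = w
    return result


def run_cohort(
    specs: list[CaseSpec],
    out_dir=None,
    arms: tuple[str, ...] = ARMS,
    selection_threshold: float = 50.0,
) -> dict:
    """Run every case, aggregate the enhancement tables and optionally
    write CSVs + a manifest.  A failing case is recorded and skipped."""
    from . import io as plio

    results: list[CaseResult] = []
    failures: dict[str, str] = {}
    for spec in specs:
        try:
            results.append(run_case(spec, arms=arms))
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            log.exception("case %s failed", spec.name)
            failures[spec.name] = f"{type(exc).__name__}: {exc}"

    records = [r for res in results for r in res.records]
    records_df = pd.DataFrame([r.__dict__ for r in records])
    included = [r for r in results if r.included]
    summary_source = [rec for res in included for rec in res.records] or records
    summary = cohort_summary(summary_source) if records else pd.DataFrame()
    case_rows = [
        {
            "case": res.spec.name,
            "included": res.included,
            **res.oar_max_physical_dose,
            **res.metrics,
        }
        for res in results
    ]
    cases_df = pd.DataFrame(case_rows)
    out = {
        "results": results,
        "records": records_df,
        "summary": summary,
        "cases": cases_df,
        "per_case": per_case_table(records) if records else pd.DataFrame(),
        "failures": failures,
    }
    if out_dir is not None:
        plio.write_cohort_outputs(out, specs, out_dir, selection_threshold)
    return out
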