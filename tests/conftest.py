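"""Shared fixtures.

The canonical-case fixtures are session-scoped because planning the
three delivery arms and the strategy screen are the expensive steps of
the suite; every qualitative test reads from the same solved study.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from protonlet.core import FractionationScheme, Phantom, Role, Structure, VoxelGrid
from protonlet.influence import InfluenceData
from protonlet.optimize import default_objective_template, strategy_grid_search
from protonlet.pipeline import CaseSpec, build_case, canonical_case, run_case


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def make_influence(dose_dense: np.ndarray, let_dense: np.ndarray, grid=None) -> InfluenceData:
    """Build InfluenceData from dense (n_spots, n_voxels) arrays with a
    shared support (let entries are kept only where dose > 0)."""
    dose_dense = np.asarray(dose_dense, float)
    let_dense = np.asarray(let_dense, float)
    if grid is None:
        grid = VoxelGrid((dose_dense.shape[1], 1, 1), (1.0, 1.0, 1.0))
    mask = dose_dense > 0
    dose = sparse.csr_matrix(np.where(mask, dose_dense, 0.0))
    let = sparse.csr_matrix(np.where(mask, let_dense, 0.0))
    let.indices = dose.indices.copy()
    let.indptr = dose.indptr.copy()
    return InfluenceData(dose=dose, let=let, grid=grid, cutoff=0.0)


@pytest.fixture()
def influence_factory():
    return make_influence


def random_influence(rng, n_spots=6, n_vox=24, density=0.6):
    dose = rng.uniform(0.2, 2.0, (n_spots, n_vox))
    dose[rng.random((n_spots, n_vox)) > density] = 0.0
    # Ensure every voxel keeps at least one contributor.
    for v in range(n_vox):
        if not (dose[:, v] > 0).any():
            dose[rng.integers(n_spots), v] = rng.uniform(0.2, 2.0)
    let = rng.uniform(0.3, 12.0, (n_spots, n_vox))
    return make_influence(dose, let)


@pytest.fixture()
def random_influence_factory():
    return random_influence


def single_voxel_phantom(dose_goal: float = 2.0) -> Phantom:
    grid = VoxelGrid((1, 1, 1), (2.0, 2.0, 2.0))
    target = Structure(
        "target", Role.TARGET_HIGH, np.ones((1, 1, 1), bool),
        prescription_per_fraction=dose_goal,
    )
    return Phantom(grid=grid, structures=[target])


@pytest.fixture()
def tiny_case_spec():
    """A fast-running case for CLI and integration smoke tests."""
    return CaseSpec(
        name="tiny",
        seed=7,
        grid_shape=(40, 40, 1),
        target_size_mm=16.0,
        entrance_gap_mm=10.0,
        oar_size_mm=8.0,
        arc_step=20.0,
    )


@pytest.fixture(scope="session")
def canonical_result():
    """Three delivery arms of the canonical bilateral distal-edge case,
    both RBE models evaluated."""
    return run_case(canonical_case(), keep_grids=True)


@pytest.fixture(scope="session")
def canonical_unilateral_spec():
    return CaseSpec(name="canonical_unilateral", seed=1234, arrangement="unilateral_2beam")


@pytest.fixture(scope="session")
def canonical_screen(canonical_unilateral_spec):
    """Full cap x threshold strategy screen on the unilateral sibling of
    the canonical case, where the LET constraint binds hardest."""
    from protonlet.influence import compute_influence

    spec = canonical_unilateral_spec
    phantom, pbs_beams, _ = build_case(spec)
    infl = compute_influence(phantom, pbs_beams)
    frac = FractionationScheme(spec.n_fractions)
    prescription = frac.total_dose(Role(spec.target_role))
    objectives = default_objective_template(phantom, prescription)
    return strategy_grid_search(
        infl,
        phantom,
        objectives,
        ["brainstem", "optic_nerve"],
        prescription,
        fractionation=frac,
        let_weight=spec.let_weight,
    )
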