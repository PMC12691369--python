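"""McMahon and McNamara RBE models and RBE-weighted dose grids."""

import math

import numpy as np
import pytest

from protonlet.core import DoseGrid, FractionationScheme, LETGrid, Role, VoxelGrid
from protonlet.phantom import OARSpec, PhantomConfig, TargetSpec, build_phantom
from protonlet.rbe import (
    RBEModelParams,
    assign_tissue_map,
    compute_rbe_dose,
    rbe_max,
    rbe_mcmahon,
    rbe_mcnamara,
    rbe_min,
)


class TestMcMahon:
    def test_photon_limit(self):
        assert rbe_mcmahon(0.0) == 1.0

    def test_slope_is_kappa(self):
        assert rbe_mcmahon(1.0) == pytest.approx(1.055, abs=1e-15)
        assert rbe_mcmahon(2.5) == pytest.approx(1.0 + 0.055 * 2.5, abs=1e-15)

    def test_negative_let_rejected(self):
        with pytest.raises(ValueError):
            rbe_mcmahon(-0.1)


class TestMcNamaraAsymptotes:
    @pytest.mark.parametrize("ab", [1.0, 2.5, 10.0])
    def test_rbe_max_intercept(self, ab):
        assert rbe_max(0.0, ab) == pytest.approx(0.99064, abs=1e-15)

    @pytest.mark.parametrize("ab", [1.0, 2.5, 10.0])
    def test_rbe_min_intercept(self, ab):
        assert rbe_min(0.0, ab) == pytest.approx(1.1012, abs=1e-15)

    def test_rbe_max_slope_at_unit_alpha_beta(self):
        assert rbe_max(1.0, 1.0) - rbe_max(0.0, 1.0) == pytest.approx(0.35605, abs=1e-12)

    def test_rbe_min_slope_magnitude_at_unit_alpha_beta(self):
        assert abs(rbe_min(1.0, 1.0) - rbe_min(0.0, 1.0)) == pytest.approx(
            0.0038703, abs=1e-12
        )

    def test_rbe_max_hand_value(self):
        # 0.99064 + 0.35605 * 2.5 / 2.5
        assert rbe_max(2.5, 2.5) == pytest.approx(0.99064 + 0.35605, rel=1e-14)

    def test_rbe_min_hand_value(self):
        expected = 1.1012 - 0.0038703 * math.sqrt(2.5) * 10.0
        assert rbe_min(10.0, 2.5) == pytest.approx(expected, rel=1e-14)

    def test_rbe_min_floored_with_warning(self):
        with pytest.warns(RuntimeWarning, match="floor"):
            out = rbe_min(100.0, 100.0)
        assert out == 0.0

    def test_invalid_alpha_beta_rejected(self):
        with pytest.raises(ValueError):
            rbe_max(1.0, 0.0)
        with pytest.raises(ValueError):
            rbe_min(1.0, -2.0)


class TestMcNamaraFull:
    def test_low_dose_limit_is_rbe_max(self):
        for let_d, ab in [(0.0, 2.5), (3.0, 2.5), (5.0, 10.0)]:
            got = rbe_mcnamara(1e-6, let_d, ab)
            assert got == pytest.approx(rbe_max(let_d, ab), rel=1e-4)

    def test_high_dose_limit_is_rbe_min(self):
        for let_d, ab in [(0.0, 2.5), (3.0, 2.5), (5.0, 10.0)]:
            got = rbe_mcnamara(1e6, let_d, ab)
            assert got == pytest.approx(rbe_min(let_d, ab), rel=1e-4)

    def test_hand_value_at_two_gray(self):
        # (1/4) * (sqrt(6.25 + 4*2*2.5*0.99064 + 16*1.1012^2) - 2.5)
        expected = (
            math.sqrt(6.25 + 4 * 2 * 2.5 * 0.99064 + 16 * 1.1012**2) - 2.5
        ) / 4.0
        assert rbe_mcnamara(2.0, 0.0, 2.5) == pytest.approx(expected, rel=1e-14)

    def test_strictly_decreasing_in_dose_when_max_exceeds_min(self):
        dp = np.logspace(-2, 2, 40)
        for let_d in (1.0, 3.0, 8.0):
            for ab in (1.0, 2.5, 10.0):
                vals = rbe_mcnamara(dp, let_d, ab)
                if rbe_max(let_d, ab) > rbe_min(let_d, ab):
                    assert np.all(np.diff(vals) < 0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            rbe_mcnamara(-1.0, 1.0, 2.5)


class TestTissueMap:
    @pytest.fixture()
    def phantom(self):
        return build_phantom(
            PhantomConfig(
                targets=(TargetSpec(size_mm=(20.0,) * 3),),
                oars=(OARSpec(gap_mm=-12.0),),  # deliberately overlapping
                allow_overlap=True,
            )
        )

    def test_assignments_and_oar_precedence(self, phantom):
        ab = assign_tissue_map(phantom)
        target = phantom.structure("ctv_high").mask
        oar = phantom.structure("brainstem").mask
        overlap = target & oar
        assert overlap.any()
        assert np.all(ab[oar] == 2.5)
        assert np.all(ab[target & ~oar] == 10.0)
        assert np.all(ab[overlap] == 2.5)  # OAR wins
        assert np.all(ab[~target & ~oar] == 2.5)  # conservative default


class TestComputeRBEDose:
    def _grids(self, dose_vals, let_vals, n_fractions=33):
        shape = dose_vals.shape
        grid = VoxelGrid(shape, (2.0, 2.0, 2.0))
        frac = FractionationScheme(n_fractions)
        return (
            DoseGrid(dose_vals, grid, frac),
            LETGrid(let_vals, grid),
        )

    def test_mcmahon_zero_let_reproduces_physical_dose(self, rng):
        dose_vals = rng.uniform(0, 70, (4, 3, 1))
        dose, let = self._grids(dose_vals, np.zeros((4, 3, 1)))
        res = compute_rbe_dose(dose, let, np.full((4, 3, 1), 2.5), "mcmahon")
        assert np.array_equal(res.rbe_model_dose.values, dose_vals)
        assert np.allclose(res.rbe11_dose.values, 1.1 * dose_vals, rtol=1e-15)

    def test_mcmahon_uniform_let_is_constant_multiple(self, rng):
        dose_vals = rng.uniform(0, 70, (4, 3, 1))
        dose, let = self._grids(dose_vals, np.full((4, 3, 1), 3.0))
        res = compute_rbe_dose(dose, let, np.full((4, 3, 1), 2.5), "mcmahon")
        assert np.allclose(
            res.rbe_model_dose.values, (1 + 0.055 * 3.0) * dose_vals, rtol=1e-14
        )

    def test_mcnamara_matches_scalar_loop_oracle(self, rng):
        shape = (5, 5, 2)
        dose_vals = rng.uniform(0, 70, shape)
        let_vals = rng.uniform(0, 10, shape)
        ab_vals = rng.choice([2.5, 10.0], size=shape)
        dose, let = self._grids(dose_vals, let_vals)
        res = compute_rbe_dose(dose, let, ab_vals, "mcnamara")
        n = 33
        for idx in np.ndindex(shape):
            dp = dose_vals[idx] / n
            ab = ab_vals[idx]
            L = let_vals[idx]
            rmax = 0.99064 + 0.35605 * L / ab
            rmin = 1.1012 - 0.0038703 * math.sqrt(ab) * L
            if dp < 1e-6:
                rbe = rmax
            else:
                rbe = (
                    math.sqrt(ab**2 + 4 * dp * ab * rmax + 4 * dp**2 * rmin**2) - ab
                ) / (2 * dp)
            expected = n * rbe * dp
            assert res.rbe_model_dose.values[idx] == pytest.approx(
                expected, rel=1e-10, abs=1e-12
            )

    def test_models_agree_at_photon_limit_intercepts(self, rng):
        dose_vals = rng.uniform(1, 70, (3, 3, 1))
        dose, let = self._grids(dose_vals, np.zeros((3, 3, 1)))
        mcm = compute_rbe_dose(dose, let, np.full((3, 3, 1), 2.5), "mcmahon")
        mcn = compute_rbe_dose(dose, let, np.full((3, 3, 1), 2.5), "mcnamara")
        assert np.allclose(mcm.rbe, 1.0)
        dp = dose_vals / 33
        expected = (
            np.sqrt(2.5**2 + 4 * dp * 2.5 * 0.99064 + 4 * dp**2 * 1.1012**2) - 2.5
        ) / (2 * dp)
        assert np.allclose(mcn.rbe, expected, rtol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        dose, let = self._grids(rng.uniform(0, 1, (3, 3, 1)), rng.uniform(0, 1, (3, 3, 1)))
        with pytest.raises(ValueError, match="congruent"):
            compute_rbe_dose(dose, let, np.full((4, 4, 1), 2.5), "mcmahon")

    def test_unknown_model_rejected(self, rng):
        dose, let = self._grids(rng.uniform(0, 1, (2, 2, 1)), rng.uniform(0, 1, (2, 2, 1)))
        with pytest.raises(ValueError, match="unknown RBE model"):
            compute_rbe_dose(dose, let, np.full((2, 2, 1), 2.5), "wedenberg")

    def test_coefficient_overrides_respected(self):
        params = RBEModelParams(kappa=0.1)
        assert rbe_mcmahon(2.0, params) == pytest.approx(1.2)
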