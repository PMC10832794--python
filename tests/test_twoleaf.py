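"""Two-leaf decomposition: fractions, LAI partition and component solve."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopygpp.synth import CampaignTruth, group_truth, synth_angular_indices
from canopygpp.twoleaf import (
    FractionError,
    GeometryError,
    TwoLeafConfig,
    background_fraction,
    decompose_scan,
    fractions_for_scan,
    interpolate_lai,
    shaded_fraction,
    solve_sun_shade,
    sunlit_fraction,
    sunlit_shaded_lai,
    total_canopy_index,
)

CFG = TwoLeafConfig()


class TestFractions:
    def test_bare_ground_background_is_one(self):
        assert background_fraction(0.0, 30.0, CFG) == 1.0

    def test_peak_lai_nadir_worked_value(self):
        # exp(-0.5 * 0.9 * 7.7) = exp(-3.465), independent scalar evaluation
        got = background_fraction(7.7, 0.0, CFG)
        assert got == pytest.approx(math.exp(-0.5 * 0.9 * 7.7), abs=1e-12)
        assert got == pytest.approx(0.0313, abs=5e-5)

    def test_background_decreases_with_view_zenith(self):
        vals = [background_fraction(4.0, t, CFG) for t in (0, 20, 40, 60, 80)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_zenith(self):
        with pytest.raises(GeometryError):
            background_fraction(4.0, 90.0, CFG)

    def test_sunlit_identity_case(self):
        cfg = TwoLeafConfig(leaf_reflectance_670=0.05)
        assert sunlit_fraction(0.05, cfg, p_vg=0.0) == pytest.approx(1.0)

    def test_sunlit_ratio_arithmetic(self):
        assert sunlit_fraction(0.03, CFG, p_vg=0.1) == pytest.approx(0.6)

    def test_sunlit_clamped_to_available_fraction(self):
        cfg = TwoLeafConfig(leaf_reflectance_670=0.05)
        assert sunlit_fraction(0.0495, cfg, p_vg=0.05) == pytest.approx(0.95)

    def test_shaded_arithmetic_and_boundary(self):
        assert shaded_fraction(0.6, 0.1) == pytest.approx(0.3)
        assert shaded_fraction(0.9, 0.1) == pytest.approx(0.0)
        with pytest.raises(FractionError):
            shaded_fraction(0.9, 0.2)

    @given(
        lai=st.floats(0.1, 9.0),
        theta=st.floats(0.0, 80.0),
        refl=st.floats(0.0, 0.06),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_closure_over_sampled_inputs(self, lai, theta, refl):
        p_vg = background_fraction(lai, theta, CFG)
        p_t = sunlit_fraction(refl, CFG, p_vg)
        p_s = shaded_fraction(p_t, p_vg)
        assert p_t + p_s + p_vg == pytest.approx(1.0, abs=1e-12)


class TestLAIPartition:
    def test_empty_canopy(self):
        assert sunlit_shaded_lai(0.0, 30.0, CFG) == (0.0, 0.0)

    def test_peak_lai_nadir_worked_values(self):
        l_sun, l_sh = sunlit_shaded_lai(7.7, 0.0, CFG)
        assert l_sun == pytest.approx(2 * (1 - math.exp(-0.5 * 0.9 * 7.7)), abs=1e-12)
        assert l_sun == pytest.approx(1.9374, abs=5e-4)
        assert l_sh == pytest.approx(7.7 - l_sun, abs=1e-12)

    @given(lai=st.floats(0.0, 12.0), theta=st.floats(0.0, 85.0))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_lai_closure_exact(self, lai, theta):
        l_sun, l_sh = sunlit_shaded_lai(lai, theta, CFG)
        # identity up to one ulp of floating-point re-addition
        assert l_sun + l_sh == pytest.approx(lai, rel=1e-15, abs=1e-15)

    def test_saturation_limit_at_high_lai(self):
        theta = 30.0
        l_sun, _ = sunlit_shaded_lai(500.0, theta, CFG)
        assert l_sun == pytest.approx(2 * math.cos(math.radians(theta)), rel=1e-6)
        assert background_fraction(500.0, theta, CFG) == pytest.approx(0.0, abs=1e-12)


class TestComponentSolve:
    def _fractions(self, n, rng):
        rows = []
        for _ in range(n):
            theta = rng.uniform(0, 60)
            p_vg = background_fraction(4.0, theta, CFG)
            p_t = (1 - p_vg) * rng.uniform(0.2, 0.9)
            rows.append((p_t, 1 - p_t - p_vg, p_vg, theta))
        from canopygpp.twoleaf import ComponentFractions

        return [ComponentFractions(*r) for r in rows]

    def test_exact_recovery(self, rng):
        fracs = self._fractions(40, rng)
        rho_sun, rho_sh = -0.02, -0.06
        obs = pd.DataFrame({"pri": [f.p_t * rho_sun + f.p_s * rho_sh for f in fracs]})
        got_sun, got_sh, diag = solve_sun_shade(obs, fracs, "pri")
        assert got_sun == pytest.approx(rho_sun, abs=1e-8)
        assert got_sh == pytest.approx(rho_sh, abs=1e-8)
        assert diag["residual_rms"] < 1e-12

    def test_degenerate_equal_components(self, rng):
        # with p_vg = 0 every observation equals c; solution is (c, c)
        from canopygpp.twoleaf import ComponentFractions

        fracs = [
            ComponentFractions(p, 1 - p, 0.0, 30.0)
            for p in rng.uniform(0.1, 0.9, 20)
        ]
        obs = pd.DataFrame({"sif": np.full(20, 0.07)})
        got_sun, got_sh, _ = solve_sun_shade(obs, fracs, "sif")
        assert got_sun == pytest.approx(0.07, abs=1e-9)
        assert got_sh == pytest.approx(0.07, abs=1e-9)

    def test_collinear_fractions_rejected(self):
        from canopygpp.twoleaf import ComponentFractions

        fracs = [ComponentFractions(0.5, 0.5, 0.0, 30.0)] * 10
        obs = pd.DataFrame({"pri": np.full(10, -0.05)})
        with pytest.raises(FractionError):
            solve_sun_shade(obs, fracs, "pri")

    def test_unbiased_under_symmetric_noise(self, rng):
        fracs = self._fractions(60, rng)
        rho_sun, rho_sh = 0.12, 0.04
        clean = np.array([f.p_t * rho_sun + f.p_s * rho_sh for f in fracs])
        est = []
        for _ in range(200):
            obs = pd.DataFrame({"sif": clean + rng.normal(0, 0.01, 60)})
            est.append(solve_sun_shade(obs, fracs, "sif")[:2])
        bias = np.mean(est, axis=0) - (rho_sun, rho_sh)
        assert np.abs(bias).max() < 0.002  # ~3 sigma of the Monte-Carlo mean


class TestTotalIndex:
    def test_convex_combination_identity(self):
        assert total_canopy_index(0.05, 0.05, 2.0, 5.0) == pytest.approx(0.05)

    def test_worked_weighting(self):
        got = total_canopy_index(0.1, 0.04, 1.9374, 5.7626)
        assert got == pytest.approx(0.0551, abs=1e-4)

    def test_boundary_no_shaded_lai(self):
        assert total_canopy_index(0.1, 0.04, 2.0, 0.0) == pytest.approx(0.1)

    def test_zero_lai_rejected(self):
        with pytest.raises(ValueError):
            total_canopy_index(0.1, 0.04, 0.0, 0.0)

    @given(
        rho_sun=st.floats(-0.2, 0.3),
        rho_sh=st.floats(-0.2, 0.3),
        l_sun=st.floats(0.01, 2.0),
        l_sh=st.floats(0.0, 8.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_total_bounded_by_components(self, rho_sun, rho_sh, l_sun, l_sh):
        tot = total_canopy_index(rho_sun, rho_sh, l_sun, l_sh)
        lo, hi = min(rho_sun, rho_sh), max(rho_sun, rho_sh)
        assert lo - 1e-12 <= tot <= hi + 1e-12


class TestScanDecomposition:
    @pytest.mark.parametrize("which", ["pri", "sif"])
    def test_end_to_end_recovery_from_forward_mixture(self, which):
        truth = CampaignTruth(seed=5)
        gt = group_truth(truth, 238, 3)
        idx = synth_angular_indices(truth, 238, 3, noise=False)
        res = decompose_scan(idx, gt["lai"], gt["theta_s"], which, truth.twoleaf_config())
        key = "rho_sun_" + which
        assert res.rho_sun == pytest.approx(gt[key], abs=1e-6)
        assert res.rho_sh == pytest.approx(gt["rho_sh_" + which], abs=1e-6)
        expected_tot = gt["sif_tot"] if which == "sif" else gt["pri_tot"]
        assert res.rho_tot == pytest.approx(expected_tot, abs=1e-6)
        assert res.l_sun + res.l_sh == pytest.approx(gt["lai"], abs=1e-12)

    def test_fraction_closure_on_processed_scan(self):
        truth = CampaignTruth(seed=5)
        gt = group_truth(truth, 238, 3)
        idx = synth_angular_indices(truth, 238, 3, noise=False)
        fracs = fractions_for_scan(idx, gt["lai"], truth.twoleaf_config())
        total = np.array([f.p_t + f.p_s + f.p_vg for f in fracs])
        np.testing.assert_allclose(total, 1.0, atol=1e-12)


def test_lai_interpolation_linear_and_clamped():
    survey = pd.DataFrame({"doy": [215, 222, 229], "lai": [5.0, 6.4, 7.0]})
    out = interpolate_lai(survey, [215, 218.5, 222, 240])
    assert out.iloc[0] == 5.0
    assert out.iloc[1] == pytest.approx(5.7)
    assert out.iloc[3] == 7.0  # held at the nearest measurement
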