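"""Kernel values, LSRT inversion recovery and hotspot extraction."""

import math

import numpy as np
import pytest

from canopygpp.brdf import (
    BRDFFit,
    InsufficientDataError,
    KernelParams,
    fit_brdf,
    hotspot_value,
    li_sparse_kernel,
    ross_thick_kernel,
)


def _ross_thick_oracle(tv_deg, ts_deg, dphi_deg):
    """Independent scalar evaluation of the Ross-Thick closed form."""
    tv, ts, dp = map(math.radians, (tv_deg, ts_deg, dphi_deg))
    cos_xi = math.cos(ts) * math.cos(tv) + math.sin(ts) * math.sin(tv) * math.cos(dp)
    xi = math.acos(max(-1.0, min(1.0, cos_xi)))
    return ((math.pi / 2 - xi) * math.cos(xi) + math.sin(xi)) / (
        math.cos(ts) + math.cos(tv)
    ) - math.pi / 4


def _li_sparse_oracle(tv_deg, ts_deg, dphi_deg, h_b=2.0, b_r=1.0):
    """Independent scalar evaluation of the non-reciprocal Li-Sparse form."""
    tv = math.atan(b_r * math.tan(math.radians(tv_deg)))
    ts = math.atan(b_r * math.tan(math.radians(ts_deg)))
    dp = math.radians(dphi_deg)
    cos_xi = math.cos(ts) * math.cos(tv) + math.sin(ts) * math.sin(tv) * math.cos(dp)
    sec_v, sec_s = 1.0 / math.cos(tv), 1.0 / math.cos(ts)
    d2 = math.tan(ts) ** 2 + math.tan(tv) ** 2 - 2 * math.tan(ts) * math.tan(tv) * math.cos(dp)
    cos_t = h_b * math.sqrt(max(d2, 0.0) + (math.tan(ts) * math.tan(tv) * math.sin(dp)) ** 2) / (
        sec_s + sec_v
    )
    cos_t = max(-1.0, min(1.0, cos_t))
    t = math.acos(cos_t)
    overlap = (t - math.sin(t) * cos_t) * (sec_s + sec_v) / math.pi
    return overlap - sec_s - sec_v + 0.5 * (1 + cos_xi) * sec_v


GEOMS = [(30, 30, 0), (30, 30, 90), (45, 20, 135), (60, 50, 180), (10, 55, 60)]


class TestKernels:
    def test_both_kernels_vanish_at_nadir_overhead(self):
        assert ross_thick_kernel(0, 0, 0) == pytest.approx(0.0, abs=1e-12)
        assert li_sparse_kernel(0, 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_ross_thick_reciprocity(self):
        for tv, ts, dp in GEOMS:
            assert ross_thick_kernel(tv, ts, dp) == pytest.approx(
                ross_thick_kernel(ts, tv, dp), abs=1e-12
            )

    @pytest.mark.parametrize("tv,ts,dp", GEOMS)
    def test_ross_thick_matches_scalar_oracle(self, tv, ts, dp):
        assert ross_thick_kernel(tv, ts, dp) == pytest.approx(
            _ross_thick_oracle(tv, ts, dp), abs=1e-12
        )

    @pytest.mark.parametrize("tv,ts,dp", GEOMS)
    def test_li_sparse_matches_scalar_oracle(self, tv, ts, dp):
        assert li_sparse_kernel(tv, ts, dp) == pytest.approx(
            _li_sparse_oracle(tv, ts, dp), abs=1e-12
        )

    def test_li_sparse_identity_transform_when_b_equals_r(self):
        # b/r = 1 leaves equivalent angles equal to the true angles, so
        # changing only h/b changes the overlap term, not the phase term
        base = li_sparse_kernel(35, 25, 40, KernelParams(2.0, 1.0))
        assert base == pytest.approx(_li_sparse_oracle(35, 25, 40, 2.0, 1.0), abs=1e-12)

    def test_backscatter_exceeds_forward_scatter(self):
        back = li_sparse_kernel(40, 30, 0)
        forward = li_sparse_kernel(40, 30, 180)
        assert back > forward


def _random_scan(rng, n):
    tv = rng.uniform(0, 60, n)
    phi_v = rng.uniform(0, 360, n)
    ts = 35.0
    phi_s = 150.0
    import pandas as pd

    return pd.DataFrame(
        {
            "view_zenith_deg": tv,
            "view_azimuth_deg": phi_v,
            "solar_zenith_deg": ts,
            "solar_azimuth_deg": phi_s,
        }
    )


def _forward(df, k, params=KernelParams()):
    dphi = np.abs(df["view_azimuth_deg"] - df["solar_azimuth_deg"]) % 360
    dphi = np.where(dphi > 180, 360 - dphi, dphi)
    k_l = li_sparse_kernel(df["view_zenith_deg"], df["solar_zenith_deg"], dphi, params)
    k_r = ross_thick_kernel(df["view_zenith_deg"], df["solar_zenith_deg"], dphi)
    return k[0] + k[1] * np.asarray(k_l) + k[2] * np.asarray(k_r)


class TestInversion:
    @pytest.mark.parametrize("k", [(0.05, 0.01, 0.02), (-0.07, 0.012, 0.025), (0.5, -0.1, 0.3)])
    def test_noiseless_recovery(self, rng, k):
        df = _random_scan(rng, 80)
        df["pri"] = _forward(df, k)
        fit = fit_brdf(df, "pri")
        assert (fit.k_i, fit.k_g, fit.k_v) == pytest.approx(k, abs=1e-8)
        assert fit.residual_rms < 1e-10

    def test_constant_field_gives_pure_isotropic_term(self, rng):
        df = _random_scan(rng, 60)
        df["sif"] = 0.08
        fit = fit_brdf(df, "sif")
        assert fit.k_i == pytest.approx(0.08, abs=1e-10)
        assert fit.k_g == pytest.approx(0.0, abs=1e-10)
        assert fit.k_v == pytest.approx(0.0, abs=1e-10)

    def test_row_duplication_invariance(self, rng):
        import pandas as pd

        df = _random_scan(rng, 40)
        df["pri"] = _forward(df, (-0.06, 0.01, 0.02)) + rng.normal(0, 0.002, 40)
        fit1 = fit_brdf(df, "pri")
        fit2 = fit_brdf(pd.concat([df, df], ignore_index=True), "pri")
        assert (fit2.k_i, fit2.k_g, fit2.k_v) == pytest.approx(
            (fit1.k_i, fit1.k_g, fit1.k_v), abs=1e-12
        )

    def test_row_order_invariance(self, rng):
        df = _random_scan(rng, 50)
        df["sif"] = _forward(df, (0.1, -0.015, 0.035)) + rng.normal(0, 0.004, 50)
        fit1 = fit_brdf(df, "sif")
        fit2 = fit_brdf(df.sample(frac=1.0, random_state=0), "sif")
        assert (fit2.k_i, fit2.k_g, fit2.k_v) == pytest.approx(
            (fit1.k_i, fit1.k_g, fit1.k_v), abs=1e-12
        )

    def test_too_few_rows_rejected(self, rng):
        df = _random_scan(rng, 2)
        df["pri"] = 0.0
        with pytest.raises(InsufficientDataError):
            fit_brdf(df, "pri")

    def test_coefficient_rmse_shrinks_with_sample_size(self):
        """Noise sigma propagates as ~1/sqrt(n) into coefficient RMSE."""
        k = (0.05, 0.01, 0.02)
        sigma = 0.01
        rmses = {}
        for n in (50, 200):
            errs = []
            rng = np.random.default_rng(7)
            df = _random_scan(rng, n)
            clean = _forward(df, k)
            for _ in range(200):
                df["pri"] = clean + rng.normal(0, sigma, n)
                fit = fit_brdf(df, "pri")
                errs.append([fit.k_i - k[0], fit.k_g - k[1], fit.k_v - k[2]])
            rmses[n] = np.sqrt(np.mean(np.square(errs)))
        ratio = rmses[50] / rmses[200]
        assert 1.6 < ratio < 2.5  # ideal 2.0 within sampling error

    def test_coefficient_rmse_scales_with_noise(self):
        k = (0.05, 0.01, 0.02)
        rmses = {}
        for sigma in (0.005, 0.02):
            errs = []
            rng = np.random.default_rng(11)
            df = _random_scan(rng, 100)
            clean = _forward(df, k)
            for _ in range(200):
                df["pri"] = clean + rng.normal(0, sigma, 100)
                fit = fit_brdf(df, "pri")
                errs.append([fit.k_i - k[0], fit.k_g - k[1], fit.k_v - k[2]])
            rmses[sigma] = np.sqrt(np.mean(np.square(errs)))
        ratio = rmses[0.02] / rmses[0.005]
        assert 3.5 < ratio < 4.5  # ideal 4.0 (proportional to sigma)


class TestHotspot:
    def test_nadir_sun_returns_isotropic_coefficient(self):
        fit = BRDFFit(0.07, 0.01, 0.02, 0.0, 100, 1.0)
        assert hotspot_value(fit, 0.0) == pytest.approx(0.07, abs=1e-12)

    def test_isotropic_fit_flat_at_any_sun_angle(self):
        fit = BRDFFit(0.07, 0.0, 0.0, 0.0, 100, 1.0)
        for ts in (0, 20, 45, 60):
            assert hotspot_value(fit, ts) == pytest.approx(0.07, abs=1e-12)

    def test_roundtrip_against_forward_model(self, rng):
        k = (-0.06, 0.012, 0.03)
        df = _random_scan(rng, 120)
        df["pri"] = _forward(df, k)
        fit = fit_brdf(df, "pri")
        import pandas as pd

        hot = pd.DataFrame(
            {
                "view_zenith_deg": [35.0],
                "view_azimuth_deg": [150.0],
                "solar_zenith_deg": [35.0],
                "solar_azimuth_deg": [150.0],
            }
        )
        assert hotspot_value(fit, 35.0) == pytest.approx(
            float(_forward(hot, k)[0]), abs=1e-8
        )

    def test_continuity_in_solar_zenith(self):
        fit = BRDFFit(0.05, 0.01, 0.02, 0.0, 100, 1.0)
        grid = np.linspace(0, 60, 200)
        vals = np.array([hotspot_value(fit, t) for t in grid])
        assert np.max(np.abs(np.diff(vals))) < 0.01

    def test_extrapolation_warning_beyond_measured_range(self):
        fit = BRDFFit(0.05, 0.01, 0.02, 0.0, 100, 1.0)
        with pytest.warns(UserWarning, match="extrapolates"):
            hotspot_value(fit, 70.0)
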