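"""Synthetic campaign generator with known ground truth.

Emulates a 25-day rice paddy observation campaign (13 half-hour groups
per day, 09:00-15:00) so every pipeline stage can be verified by
parameter recovery:

* downwelling irradiance with an O2-A Fraunhofer absorption dip at
  762 nm and canopy radiance with additive fluorescence (3FLD stage);
* per-angle PRI/SIF fields built either from the LSRT kernel forward
  model ('brdf' mode), from the sunlit/shaded two-leaf mixture
  ('twoleaf' mode), or their average ('mixed' mode);
* half-hourly flux series with Van't Hoff respiration, light-response
  or index-coupled GPP, noise, rainfall events, low-turbulence nights,
  out-of-range spikes and missing slots (flux stage);
* campaign-level GPP coupled linearly to the truth total-canopy SIF and
  PRI so the end-to-end regression has a known target.

Every generator is a pure function of (truth, seed): regenerating with
the same :class:`CampaignTruth` is bit-identical.

Units: flux quantities in mg CO2 m-2 s-1; the GPP-index coupling
coefficients live on the umol CO2 m-2 s-1 scale (1 mg CO2 = 22.722 umol)
matching the scale on which the regression stage operates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import brdf as _brdf
from . import twoleaf as _twoleaf
from .spectral import AngularScan, Spectrum, ViewGeometry, WhiteboardCalibration

__all__ = [
    "CampaignTruth",
    "UMOL_PER_MG_CO2",
    "solar_position",
    "lai_on",
    "lai_survey",
    "synth_solar_spectrum",
    "synth_angular_indices",
    "synth_angular_scan",
    "synth_flux_day",
    "synth_campaign",
]

#: umol CO2 per mg CO2 (molar mass 44.01 g/mol).
UMOL_PER_MG_CO2 = 1000.0 / 44.01

_DEFAULT_DOYS = (
    215, 217, 220, 222, 224, 227, 230, 232, 235, 238, 240, 243, 246,
    248, 251, 254, 256, 259, 262, 264, 267, 269, 271, 274, 277,
)

_YEAR = 2018


@dataclass(frozen=True)
class CampaignTruth:
    """Ground-truth parameters of one synthetic campaign.

    All stochastic draws are derived from ``seed`` plus the (doy, slot)
    coordinates, so the whole campaign is reproducible from this object
    alone. Defaults emulate a subtropical rice paddy across tillering to
    maturity: LAI peaking at 7.7, half-hourly groups 09:00-15:00 over 25
    days, clumping index 0.9, Van't Hoff respiration with
    re_ref = 0.22 mg m-2 s-1 and b = 0.1235 per degC, and a GPP-index
    coupling on the umol scale.
    """

    seed: int = 0
    mode: str = "twoleaf"  # 'twoleaf' | 'brdf' | 'mixed'
    doys: tuple[int, ...] = _DEFAULT_DOYS
    lat: float = 32.43
    lon: float = 116.78
    n_slots: int = 13  # half-hour groups 09:00 .. 15:00
    # canopy
    lai_start: float = 5.5
    lai_peak: float = 7.7
    lai_peak_doy: int = 224
    lai_end: float = 3.0
    omega: float = 0.9
    leaf_reflectance_670: float = 0.05
    # angular sampling: 31 azimuths x 7 zeniths, repeated with jitter
    azimuth_range: float = 150.0
    zenith_max: float = 60.0
    angle_step: float = 10.0
    n_repeats: int = 7
    angle_jitter: float = 1.5  # deg
    # index component truths (two-leaf forward model)
    sif_sun_scale: float = 0.22  # W m-2 um-1 sr-1 at full light
    sif_shade_ratio: float = 0.35
    pri_sun_base: float = -0.05
    pri_sun_light: float = -0.05
    pri_sh_base: float = -0.02
    pri_sh_light: float = -0.01
    component_jitter_pri: float = 0.003
    component_jitter_sif: float = 0.004
    # LSRT kernel truths ('brdf' mode), per index: (k_i, k_g, k_v)
    k_pri: tuple[float, float, float] = (-0.07, 0.012, 0.025)
    k_sif: tuple[float, float, float] = (0.10, -0.015, 0.035)
    # per-angle observation noise
    noise_pri: float = 0.002
    noise_sif: float = 0.004
    # spectra
    dip_depth: float = 0.6
    dip_sigma_nm: float = 1.0
    wavelength_step_nm: float = 1.0
    nir_reflectance: float = 0.5
    r570: float = 0.05
    # flux / meteorology
    re_ref: float = 0.22  # mg CO2 m-2 s-1 at t_ref
    b: float = 0.1235  # per degC
    t_ref: float = 25.0
    par_clear_max: float = 2200.0  # umol m-2 s-1
    cloudy_day_prob: float = 0.3
    sigma_nee: float = 0.02  # mg CO2 m-2 s-1
    frac_low_ustar_nights: float = 0.3
    rain_day_prob: float = 0.15
    frac_range_spikes: float = 0.01
    frac_missing: float = 0.02
    night_par_threshold: float = 5.0
    # GPP coupling (umol CO2 m-2 s-1 scale)
    a_sif: float = 118.06
    a_pri: float = -130.47
    c_gpp: float = -5.29
    gpp_max_umol: float = 22.0  # light-response ceiling outside group hours

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CampaignTruth":
        d = json.loads(text)
        for key in ("doys", "k_pri", "k_sif"):
            d[key] = tuple(d[key])
        return cls(**d)

    @property
    def slot_hours(self) -> np.ndarray:
        return 9.0 + 0.5 * np.arange(self.n_slots)

    def twoleaf_config(self) -> _twoleaf.TwoLeafConfig:
        return _twoleaf.TwoLeafConfig(
            omega=self.omega, leaf_reflectance_670=self.leaf_reflectance_670
        )


def _rng(truth: CampaignTruth, *key: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed & 0x7FFFFFFF, *key])


def _timestamp(doy: int, hour: float) -> pd.Timestamp:
    return (
        pd.Timestamp(f"{_YEAR}-01-01")
        + pd.Timedelta(days=int(doy) - 1)
        + pd.Timedelta(hours=float(hour))
    )


# ---------------------------------------------------------------------------
# environment: sun, sky, canopy
# ---------------------------------------------------------------------------

def solar_position(truth: CampaignTruth, doy: int, hour: float) -> tuple[float, float]:
    """Solar zenith and azimuth (deg) from a low-precision ephemeris.

    Declination from the standard 23.45 deg sine approximation; hour angle
    from local solar time with the site's longitude offset from the UTC+8
    reference meridian (120 deg E). Adequate for generating plausible
    geometry — the pipeline itself takes angles as data.
    """
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    solar_hour = hour + (truth.lon - 120.0) / 15.0
    h = np.deg2rad(15.0 * (solar_hour - 12.0))
    lat = np.deg2rad(truth.lat)
    cos_z = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(h)
    theta_s = float(np.rad2deg(np.arccos(np.clip(cos_z, -1.0, 1.0))))
    sin_z = np.sqrt(max(1.0 - cos_z**2, 1e-12))
    cos_az = (np.sin(decl) - np.sin(lat) * cos_z) / (np.cos(lat) * sin_z)
    az = float(np.rad2deg(np.arccos(np.clip(cos_az, -1.0, 1.0))))
    phi_s = az if solar_hour <= 12.0 else 360.0 - az
    return theta_s, phi_s


def lai_on(truth: CampaignTruth, doy) -> np.ndarray:
    """True daily LAI: linear rise to the peak, linear decline after."""
    doy = np.asarray(doy, dtype=float)
    d0, dp, d1 = truth.doys[0], truth.lai_peak_doy, truth.doys[-1]
    rise = truth.lai_start + (truth.lai_peak - truth.lai_start) * (doy - d0) / (dp - d0)
    fall = truth.lai_peak + (truth.lai_end - truth.lai_peak) * (doy - dp) / (d1 - dp)
    return np.where(doy <= dp, rise, fall)


def lai_survey(truth: CampaignTruth) -> pd.DataFrame:
    """Sparse (7-day) LAI measurements as sampled in the field."""
    doys = np.arange(truth.doys[0], truth.doys[-1] + 1, 7)
    if doys[-1] != truth.doys[-1]:
        doys = np.append(doys, truth.doys[-1])
    return pd.DataFrame({"doy": doys, "lai": lai_on(truth, doys)})


def _cloud_factor(truth: CampaignTruth, doy: int) -> float:
    rng = _rng(truth, 11, doy)
    if rng.random() < truth.cloudy_day_prob:
        return float(rng.uniform(0.2, 0.42))
    return float(rng.uniform(0.85, 1.0))


def _t_air(truth: CampaignTruth, doy: int, hour: float) -> float:
    span = truth.doys[-1] - truth.doys[0]
    t_mean = 28.0 - 8.0 * (doy - truth.doys[0]) / span
    return t_mean + 5.0 * np.sin(np.pi * (hour - 8.0) / 12.0)


def _vpd(truth: CampaignTruth, t_air: float, hour: float, cloud: float) -> float:
    es = 0.61078 * np.exp(17.27 * t_air / (t_air + 237.3))  # kPa
    rh_mid = 0.35 + 0.25 * (1.0 - cloud)  # cloudier -> moister air
    rh = rh_mid + (0.9 - rh_mid) * abs(hour - 13.0) / 13.0
    return float(es * (1.0 - min(rh, 0.98)))


def _par(truth: CampaignTruth, doy: int, hour: float, cloud: float) -> float:
    theta_s, _ = solar_position(truth, doy, hour)
    return float(truth.par_clear_max * max(np.cos(np.deg2rad(theta_s)), 0.0) * cloud)


# ---------------------------------------------------------------------------
# per-group index truth
# ---------------------------------------------------------------------------

def group_truth(truth: CampaignTruth, doy: int, slot: int) -> dict:
    """Deterministic ground truth for one half-hour group.

    Returns solar geometry, environment, the two-leaf component values
    (rho_sun/rho_sh per index), the LAI-weighted totals, and the coupled
    GPP (umol m-2 s-1, noise-free).
    """
    hour = float(truth.slot_hours[slot])
    theta_s, phi_s = solar_position(truth, doy, hour)
    cloud = _cloud_factor(truth, doy)
    par = _par(truth, doy, hour, cloud)
    t_air = _t_air(truth, doy, hour)
    vpd = _vpd(truth, t_air, hour, cloud)
    lai = float(lai_on(truth, doy))
    light = par / 2000.0

    rng = _rng(truth, 23, doy, slot)
    jit = rng.normal(size=4)
    # floors scale with the SIF amplitude so a zero-fluorescence campaign
    # (sif_sun_scale = 0) stays exactly fluorescence-free
    rho_sun_sif = truth.sif_sun_scale * light * (0.6 + 0.4 * lai / truth.lai_peak)
    rho_sun_sif = max(
        rho_sun_sif + truth.component_jitter_sif * jit[0], 0.015 * truth.sif_sun_scale
    )
    rho_sh_sif = max(
        truth.sif_shade_ratio * rho_sun_sif + truth.component_jitter_sif * jit[1],
        0.005 * truth.sif_sun_scale,
    )
    rho_sun_pri = (
        truth.pri_sun_base + truth.pri_sun_light * light
        + truth.component_jitter_pri * jit[2]
    )
    rho_sh_pri = (
        truth.pri_sh_base + truth.pri_sh_light * light
        + truth.component_jitter_pri * jit[3]
    )

    cfg = truth.twoleaf_config()
    l_sun, l_sh = _twoleaf.sunlit_shaded_lai(lai, theta_s, cfg)
    sif_tot = _twoleaf.total_canopy_index(rho_sun_sif, rho_sh_sif, l_sun, l_sh)
    pri_tot = _twoleaf.total_canopy_index(rho_sun_pri, rho_sh_pri, l_sun, l_sh)
    gpp_umol = truth.a_sif * sif_tot + truth.a_pri * pri_tot + truth.c_gpp

    return {
        "doy": doy,
        "slot": slot,
        "timestamp": _timestamp(doy, hour),
        "theta_s": theta_s,
        "phi_s": phi_s,
        "par": par,
        "t_air": t_air,
        "vpd": vpd,
        "cloud": cloud,
        "lai": lai,
        "rho_sun_sif": rho_sun_sif,
        "rho_sh_sif": rho_sh_sif,
        "rho_sun_pri": rho_sun_pri,
        "rho_sh_pri": rho_sh_pri,
        "l_sun": l_sun,
        "l_sh": l_sh,
        "sif_tot": sif_tot,
        "pri_tot": pri_tot,
        "gpp_umol": gpp_umol,
    }


def _angular_grid(
    truth: CampaignTruth, rng: np.random.Generator, n_repeats: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """View zenith/azimuth-offset samples for one rotation cycle set."""
    n_rep = truth.n_repeats if n_repeats is None else n_repeats
    az = np.arange(-truth.azimuth_range, truth.azimuth_range + 1e-9, truth.angle_step)
    zen = np.arange(0.0, truth.zenith_max + 1e-9, truth.angle_step)
    zz, aa = np.meshgrid(zen, az, indexing="ij")
    zz, aa = zz.ravel(), aa.ravel()
    zz = np.tile(zz, n_rep)
    aa = np.tile(aa, n_rep)
    if truth.angle_jitter > 0:
        zz = np.clip(zz + rng.normal(0, truth.angle_jitter, zz.size), 0.0, 89.0)
        aa = aa + rng.normal(0, truth.angle_jitter, aa.size)
    return zz, aa


def _forward_field(
    truth: CampaignTruth,
    gt: dict,
    theta_v: np.ndarray,
    phi_v: np.ndarray,
    mode: str | None = None,
) -> dict[str, np.ndarray]:
    """Noise-free per-angle PRI/SIF and sunlit fraction for one group.

    The two-leaf forward model mixes the component truths with
    angle-dependent sunlit/shaded fractions; the sunlit share among
    visible leaves rises toward the sun-view coincident (hotspot)
    direction. The BRDF forward model evaluates the LSRT superposition
    with the truth kernel coefficients.
    """
    mode = mode or truth.mode
    theta_s, phi_s = gt["theta_s"], gt["phi_s"]
    dphi = np.abs(phi_v - phi_s) % 360.0
    dphi = np.where(dphi > 180.0, 360.0 - dphi, dphi)

    cfg = truth.twoleaf_config()
    p_vg = np.exp(
        -0.5 * truth.omega * gt["lai"] / np.cos(np.deg2rad(theta_v))
    )
    cos_phase = np.cos(np.deg2rad(theta_v)) * np.cos(np.deg2rad(theta_s)) + np.sin(
        np.deg2rad(theta_v)
    ) * np.sin(np.deg2rad(theta_s)) * np.cos(np.deg2rad(dphi))
    sunlit_share = np.clip(0.5 + 0.25 * cos_phase, 0.0, 1.0)
    p_t = (1.0 - p_vg) * sunlit_share
    p_s = 1.0 - p_t - p_vg

    two = {
        "pri": p_t * gt["rho_sun_pri"] + p_s * gt["rho_sh_pri"],
        "sif": p_t * gt["rho_sun_sif"] + p_s * gt["rho_sh_sif"],
    }
    if mode == "twoleaf":
        fields = two
    else:
        k_l = _brdf.li_sparse_kernel(theta_v, theta_s, dphi)
        k_r = _brdf.ross_thick_kernel(theta_v, theta_s, dphi)
        lsrt = {
            "pri": truth.k_pri[0] + truth.k_pri[1] * k_l + truth.k_pri[2] * k_r,
            "sif": truth.k_sif[0] + truth.k_sif[1] * k_l + truth.k_sif[2] * k_r,
        }
        if mode == "brdf":
            fields = lsrt
        elif mode == "mixed":
            fields = {k: 0.5 * (two[k] + lsrt[k]) for k in two}
        else:
            raise ValueError(f"unknown forward mode {mode!r}")
    fields = dict(fields)
    fields["p_t"] = p_t
    fields["refl_670"] = cfg.leaf_reflectance_670 * p_t
    return fields


def synth_angular_indices(
    truth: CampaignTruth,
    doy: int,
    slot: int,
    mode: str | None = None,
    noise: bool = True,
    n_repeats: int | None = None,
) -> pd.DataFrame:
    """One half-hour angular index set (per-angle PRI/SIF + 670 nm refl).

    This is the index-level output of the spectral stage, generated
    directly from the forward model; use :func:`synth_angular_scan` for
    full spectra.
    """
    gt = group_truth(truth, doy, slot)
    rng = _rng(truth, 37, doy, slot)
    theta_v, az_off = _angular_grid(truth, rng, n_repeats)
    phi_v = az_off % 360.0
    fields = _forward_field(truth, gt, theta_v, phi_v, mode)
    pri = fields["pri"].copy()
    sif = fields["sif"].copy()
    if noise:
        pri = pri + rng.normal(0, truth.noise_pri, pri.size)
        sif = sif + rng.normal(0, truth.noise_sif, sif.size)
    return pd.DataFrame(
        {
            "timestamp": gt["timestamp"],
            "view_zenith_deg": theta_v,
            "view_azimuth_deg": phi_v,
            "solar_zenith_deg": gt["theta_s"],
            "solar_azimuth_deg": gt["phi_s"],
            "pri": pri,
            "sif": sif,
            "refl_670": fields["refl_670"],
            "qc_flags": np.where(sif < 0, 2, 0),
        }
    )


# ---------------------------------------------------------------------------
# full spectra
# ---------------------------------------------------------------------------

def _wavelength_grid(truth: CampaignTruth) -> np.ndarray:
    return np.arange(350.0, 800.0 + 1e-9, truth.wavelength_step_nm)


def synth_solar_spectrum(
    truth: CampaignTruth = CampaignTruth(), dip_depth: float | None = None
) -> Spectrum:
    """Smooth downwelling irradiance with a Gaussian O2-A dip at 762 nm."""
    dd = truth.dip_depth if dip_depth is None else dip_depth
    if not (0.0 <= dd < 1.0):
        raise ValueError("dip_depth must lie in [0, 1)")
    wl = _wavelength_grid(truth)
    smooth = 1.2 + 0.6 * np.exp(-(((wl - 520.0) / 260.0) ** 2))
    dip = 1.0 - dd * np.exp(-(((wl - 762.0) / truth.dip_sigma_nm) ** 2) / 2.0)
    return Spectrum(wl, smooth * dip, kind="downwelling")


def _reflectance_spectrum(
    truth: CampaignTruth, wl: np.ndarray, r531: float, r570: float, r670: float
) -> np.ndarray:
    """Piecewise reflectance with flat plateaus at every band in use.

    Flat within +/-2 nm of 531/570/670 nm and above 745 nm (so the 3FLD
    flat-reflectance assumption holds exactly over the O2-A bands);
    linear elsewhere through green-vegetation anchor points.
    """
    anchors_wl = np.array(
        [350.0, 450.0, 529.0, 533.0, 568.0, 572.0, 640.0, 668.0, 672.0,
         700.0, 745.0, 800.0]
    )
    anchors_r = np.array(
        [0.04, 0.035, r531, r531, r570, r570, 0.06, r670, r670,
         0.15, truth.nir_reflectance, truth.nir_reflectance]
    )
    return np.interp(wl, anchors_wl, anchors_r)


def _fluorescence_spectrum(truth: CampaignTruth, wl: np.ndarray, sif: float) -> np.ndarray:
    """Additive fluorescence: zero below 700 nm, ramping to a constant
    value above 740 nm (constant over the O2-A bands by construction)."""
    ramp = np.clip((wl - 700.0) / 40.0, 0.0, 1.0)
    return sif * ramp


def synth_angular_scan(
    truth: CampaignTruth,
    doy: int,
    slot: int,
    mode: str | None = None,
    noise: bool = False,
    n_repeats: int | None = None,
) -> tuple[AngularScan, WhiteboardCalibration, pd.DataFrame]:
    """One half-hour group of full directional spectra.

    Radiance is built as L = R * E + F with the whiteboard satisfying
    L' = E', so whiteboard calibration recovers R + F/E exactly; PRI
    bands carry the target per-angle PRI, the 670 nm plateau encodes the
    sunlit fraction, and the injected fluorescence equals the target SIF.
    Returns the scan, its calibration, and the truth index table.
    """
    idx = synth_angular_indices(truth, doy, slot, mode, noise=noise, n_repeats=n_repeats)
    wl = _wavelength_grid(truth)
    downwelling = synth_solar_spectrum(truth)
    cal = WhiteboardCalibration(wl, np.ones_like(wl), np.ones_like(wl))
    geoms, reflected = [], []
    for row in idx.itertuples():
        p = row.pri
        r531 = truth.r570 * (1.0 + p) / (1.0 - p)
        r = _reflectance_spectrum(truth, wl, r531, truth.r570, row.refl_670)
        f = _fluorescence_spectrum(truth, wl, row.sif)
        reflected.append(Spectrum(wl, r * downwelling.values + f, kind="reflected"))
        geoms.append(
            ViewGeometry(
                theta_v=row.view_zenith_deg,
                phi_v=row.view_azimuth_deg,
                theta_s=row.solar_zenith_deg,
                phi_s=row.solar_azimuth_deg,
            )
        )
    scan = AngularScan(
        timestamp=idx["timestamp"].iloc[0],
        geometries=geoms,
        reflected=reflected,
        downwelling=[downwelling],
    )
    return scan, cal, idx


# ---------------------------------------------------------------------------
# flux series
# ---------------------------------------------------------------------------

def synth_flux_day(
    truth: CampaignTruth,
    doy: int,
    gpp_umol_by_hour: dict[float, float] | None = None,
    noise: bool = True,
    inject_artifacts: bool = True,
) -> pd.DataFrame:
    """48 half-hourly flux records for one day.

    GPP truth follows a PAR light response scaled by LAI, overridden by
    ``gpp_umol_by_hour`` (umol m-2 s-1, keyed by decimal hour) where
    provided — the campaign generator passes the index-coupled GPP for
    the 09:00-15:00 groups. NEE = Re - GPP + noise, with configured
    fractions of rainy half-hours, low-u* nights, out-of-range spikes
    and missing slots injected on top.
    """
    rng = _rng(truth, 53, doy)
    cloud = _cloud_factor(truth, doy)
    lai = float(lai_on(truth, doy))
    rows = []
    for k in range(48):
        hour = k / 2.0
        t_air = _t_air(truth, doy, hour)
        par = _par(truth, doy, hour, cloud)
        vpd = _vpd(truth, t_air, hour, cloud)
        re = truth.re_ref * np.exp(truth.b * (t_air - truth.t_ref))
        night = par < truth.night_par_threshold
        if gpp_umol_by_hour is not None and hour in gpp_umol_by_hour:
            gpp_umol = gpp_umol_by_hour[hour]
        elif night:
            gpp_umol = 0.0
        else:
            gpp_umol = truth.gpp_max_umol * par / (par + 800.0) * lai / truth.lai_peak
        gpp_mg = gpp_umol / UMOL_PER_MG_CO2
        nee = re - gpp_mg
        if noise:
            nee += rng.normal(0, truth.sigma_nee)
        if night:
            if inject_artifacts and rng.random() < truth.frac_low_ustar_nights:
                ustar = rng.uniform(0.04, 0.12)
            else:
                ustar = rng.uniform(0.15, 0.40)
        else:
            ustar = rng.uniform(0.25, 0.55)
        rows.append(
            {
                "timestamp": _timestamp(doy, hour),
                "nee": nee,
                "t_air": t_air,
                "vpd": vpd,
                "par": par,
                "ustar": ustar,
                "rain_flag": False,
                "range_ok": True,
                "gpp_true_mg": 0.0 if night else gpp_mg,
                "re_true": re,
            }
        )
    df = pd.DataFrame(rows)
    if inject_artifacts:
        if rng.random() < truth.rain_day_prob:
            df.loc[int(rng.integers(0, 48)), "rain_flag"] = True
        spikes = rng.random(48) < truth.frac_range_spikes
        df.loc[spikes, "nee"] = rng.choice([-6.0, 6.0], size=int(spikes.sum()))
        df.loc[spikes, "range_ok"] = False
        missing = rng.random(48) < truth.frac_missing
        df.loc[missing, "nee"] = np.nan
    return df


# ---------------------------------------------------------------------------
# full campaign
# ---------------------------------------------------------------------------

def synth_campaign(
    truth: CampaignTruth,
    noise: bool = True,
    inject_artifacts: bool = True,
    n_repeats: int | None = None,
) -> dict:
    """Generate the full 25-day campaign at the index level.

    Returns a dict with keys:

    ``indices``
        concatenated per-angle index sets for all 325 groups;
    ``flux``
        half-hourly flux records for all campaign days, with the
        09:00-15:00 GPP truth coupled to the truth SIF_tot/PRI_tot via
        GPP = a_sif * SIF_tot + a_pri * PRI_tot + c (umol scale);
    ``lai``
        the sparse 7-day LAI survey;
    ``groups``
        the per-group ground-truth table (components, totals, GPP).
    """
    all_idx, all_flux, all_groups = [], [], []
    for doy in truth.doys:
        gpp_by_hour: dict[float, float] = {}
        for slot in range(truth.n_slots):
            gt = group_truth(truth, doy, slot)
            all_groups.append(gt)
            gpp_by_hour[float(truth.slot_hours[slot])] = gt["gpp_umol"]
            all_idx.append(
                synth_angular_indices(
                    truth, doy, slot, noise=noise, n_repeats=n_repeats
                )
            )
        all_flux.append(
            synth_flux_day(
                truth, doy, gpp_umol_by_hour=gpp_by_hour,
                noise=noise, inject_artifacts=inject_artifacts,
            )
        )
    return {
        "indices": pd.concat(all_idx, ignore_index=True),
        "flux": pd.concat(all_flux, ignore_index=True),
        "lai": lai_survey(truth),
        "groups": pd.DataFrame(all_groups),
    }
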