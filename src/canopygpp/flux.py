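"""Eddy-covariance flux screening, gap filling and GPP partitioning.

Half-hourly net ecosystem exchange (NEE, mg CO2 m-2 s-1; negative =
uptake) is screened with four standard rules, gap-filled, and partitioned
into ecosystem respiration Re and gross primary productivity via
GPP = Re - NEE. Nighttime NEE (no photosynthetically active radiation)
is taken as Re and fitted to the Van't Hoff exponential temperature
response Re = Re_ref * exp(B (T - T_ref)) with T_ref = 25 degC; the fitted
curve supplies daytime Re and fills missing nights, while missing daytime
slots are filled by the mean diurnal course over a +/-7 day window.

Screening rules (each removal tagged):
  a. out of instrument range,
  b. negative NEE at night,
  c. within 1 h before/after a rainfall event,
  d. nighttime friction velocity u* below threshold (default 0.13 m/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "VantHoffFit",
    "FluxScreeningConfig",
    "DegenerateFitError",
    "apply_quality_filters",
    "fit_vant_hoff",
    "fill_gaps",
    "partition_gpp",
    "process_flux",
]

REQUIRED_COLUMNS = ("timestamp", "nee", "t_air", "par", "ustar")


class DegenerateFitError(ValueError):
    """Respiration fit is unidentifiable (insufficient temperature spread)."""


@dataclass(frozen=True)
class FluxScreeningConfig:
    """Thresholds for the four screening rules and derived quantities."""

    ustar_threshold: float = 0.13  # m s-1, nighttime turbulence screen
    night_par_threshold: float = 5.0  # umol m-2 s-1; below = night
    nee_range: float = 3.0  # |NEE| plausibility window, mg m-2 s-1
    rain_window_hours: float = 1.0
    diurnal_window_days: int = 7
    t_ref: float = 25.0  # degC, Van't Hoff reference temperature


@dataclass
class VantHoffFit:
    """Fitted exponential temperature response of nighttime respiration."""

    re_ref: float  # mg CO2 m-2 s-1 at t_ref
    b: float  # degC-1
    t_ref: float
    n_fit: int
    rss: float

    def __call__(self, t_air) -> np.ndarray:
        return self.re_ref * np.exp(self.b * (np.asarray(t_air, dtype=float) - self.t_ref))


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"flux table missing required column {col!r}")
    ts = pd.to_datetime(records["timestamp"])
    if ts.duplicated().any():
        raise ValueError("duplicated timestamps in flux table")
    if not ts.is_monotonic_increasing:
        raise ValueError("flux table must be time-ordered")
    df = records.copy()
    df["timestamp"] = ts
    return df


def apply_quality_filters(
    records: pd.DataFrame, cfg: FluxScreeningConfig = FluxScreeningConfig()
) -> pd.DataFrame:
    """Tag each half-hour with its screening outcome.

    Adds ``is_night`` (PAR below threshold) and a ``qc`` column: 'ok' for
    survivors, otherwise the first matching rule tag among
    'a_range', 'b_night_negative', 'c_rain_window', 'd_low_ustar'.
    Screened-out rows keep their data but their NEE is treated as a gap
    downstream. Idempotent: re-screening survivors changes nothing.
    """
    df = _validate(records)
    df["is_night"] = df["par"].to_numpy(dtype=float) < cfg.night_par_threshold

    nee = df["nee"].to_numpy(dtype=float)
    night = df["is_night"].to_numpy()

    if "range_ok" in df.columns:
        rule_a = ~df["range_ok"].to_numpy(dtype=bool)
    else:
        rule_a = np.abs(nee) > cfg.nee_range
    rule_a |= np.abs(nee) > cfg.nee_range

    rule_b = night & (nee < 0.0)

    rain = (
        df["rain_flag"].to_numpy(dtype=bool)
        if "rain_flag" in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    rule_c = np.zeros(len(df), dtype=bool)
    if rain.any():
        ts = df["timestamp"].to_numpy()
        window = np.timedelta64(int(cfg.rain_window_hours * 3600), "s")
        rain_times = ts[rain]
        for rt in rain_times:
            rule_c |= (ts >= rt - window) & (ts <= rt + window)

    ustar = df["ustar"].to_numpy(dtype=float)
    rule_d = night & (ustar < cfg.ustar_threshold)

    qc = np.full(len(df), "ok", dtype=object)
    # later rules do not overwrite earlier tags: precedence a > b > c > d
    for tag, mask in (
        ("d_low_ustar", rule_d),
        ("c_rain_window", rule_c),
        ("b_night_negative", rule_b),
        ("a_range", rule_a),
    ):
        qc[mask] = tag
    df["qc"] = qc
    return df


def fit_vant_hoff(
    night_records: pd.DataFrame, t_ref: float = 25.0
) -> VantHoffFit:
    """Nonlinear LS fit of nighttime NEE to Re_ref * exp(B (T - T_ref)).

    ``night_records`` should be screened nighttime half-hours (NEE taken as
    Re). Requires >= 10 records spanning >= 5 degC so B is identifiable.
    """
    df = night_records.dropna(subset=["nee", "t_air"])
    t = df["t_air"].to_numpy(dtype=float)
    y = df["nee"].to_numpy(dtype=float)
    if len(df) < 10 or (t.max() - t.min()) < 5.0:
        raise DegenerateFitError(
            "need >= 10 night records spanning >= 5 degC to fit respiration"
        )

    def model(tt, re_ref, b):
        return re_ref * np.exp(b * (tt - t_ref))

    p0 = (max(float(np.mean(y)), 1e-6), 0.1)
    popt, _ = curve_fit(model, t, y, p0=p0, maxfev=10000)
    resid = y - model(t, *popt)
    return VantHoffFit(
        re_ref=float(popt[0]),
        b=float(popt[1]),
        t_ref=t_ref,
        n_fit=len(df),
        rss=float(np.sum(resid**2)),
    )


def fill_gaps(
    records: pd.DataFrame,
    fit: VantHoffFit,
    cfg: FluxScreeningConfig = FluxScreeningConfig(),
) -> pd.DataFrame:
    """Fill screened-out or missing NEE values.

    Daytime gaps take the mean diurnal course: the mean of valid NEE in the
    same half-hour slot within +/- ``diurnal_window_days`` days. Nighttime
    gaps take the Van't Hoff curve at the record's air temperature. Adds
    ``nee_filled`` and a ``filled`` flag ('no', 'diurnal', 'vant_hoff',
    'unfillable'); never changes valid records.
    """
    df = records.copy()
    if "qc" not in df.columns:
        raise ValueError("records must be screened (run apply_quality_filters first)")
    valid = (df["qc"] == "ok") & df["nee"].notna()
    nee_filled = df["nee"].to_numpy(dtype=float).copy()
    filled = np.full(len(df), "no", dtype=object)

    ts = pd.to_datetime(df["timestamp"])
    slot = ts.dt.hour * 2 + ts.dt.minute // 30
    date = ts.dt.normalize()
    night = df["is_night"].to_numpy()
    window = pd.Timedelta(days=cfg.diurnal_window_days)

    gap_idx = np.flatnonzero(~valid.to_numpy())
    for i in gap_idx:
        if night[i]:
            t_air = df["t_air"].iloc[i]
            if pd.isna(t_air):
                filled[i] = "unfillable"
                continue
            nee_filled[i] = float(fit(t_air))
            filled[i] = "vant_hoff"
        else:
            donors = valid.to_numpy() & (slot == slot.iloc[i]).to_numpy()
            donors &= (abs(date - date.iloc[i]) <= window).to_numpy()
            if not donors.any():
                filled[i] = "unfillable"
                continue
            nee_filled[i] = float(df.loc[donors, "nee"].mean())
            filled[i] = "diurnal"

    df["nee_filled"] = nee_filled
    df["filled"] = filled
    return df


def partition_gpp(
    records: pd.DataFrame,
    fit: VantHoffFit,
) -> pd.DataFrame:
    """Partition gap-filled NEE into Re and GPP via GPP = Re - NEE.

    Daytime Re is the Van't Hoff curve at each record's air temperature.
    At night there is no photosynthesis, so the (gap-filled) NEE is itself
    Re and GPP = Re - NEE = 0 by construction; the identity
    gpp + nee - re = 0 therefore holds on every processed record.
    Records without temperature get undefined Re/GPP.
    """
    df = records.copy()
    nee_col = "nee_filled" if "nee_filled" in df.columns else "nee"
    t = df["t_air"].to_numpy(dtype=float)
    re = np.where(np.isfinite(t), fit(np.nan_to_num(t, nan=fit.t_ref)), np.nan)
    nee = df[nee_col].to_numpy(dtype=float)
    night = df["is_night"].to_numpy(dtype=bool)
    re = np.where(night & np.isfinite(nee), nee, re)
    gpp = re - nee
    gpp = np.where(np.isfinite(re) & np.isfinite(nee), gpp, np.nan)
    df["re"] = re
    df["gpp"] = gpp
    return df


def process_flux(
    records: pd.DataFrame,
    cfg: FluxScreeningConfig = FluxScreeningConfig(),
) -> tuple[pd.DataFrame, VantHoffFit]:
    """Screen, fit respiration, fill gaps and partition in one call."""
    screened = apply_quality_filters(records, cfg)
    nights = screened[(screened["qc"] == "ok") & screened["is_night"]]
    fit = fit_vant_hoff(nights, t_ref=cfg.t_ref)
    filled = fill_gaps(screened, fit, cfg)
    return partition_gpp(filled, fit), fit
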