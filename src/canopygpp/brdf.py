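"""Kernel-driven BRDF fitting and hotspot extraction for angular PRI/SIF.

Each half-hour angular index set is modelled as a linear superposition

    rho(theta_v, theta_s, dphi) = k_i + k_g * K_L + k_v * K_R

with K_L the Li-Sparse geometric kernel and K_R the Ross-Thick volumetric
kernel (the LSRT pair). The fitted surface is evaluated at the hotspot —
the sun-view coincident geometry (theta_v = theta_s, dphi = 0) where
shadows are hidden — to obtain PRI_hs and SIF_hs, which normalizes the
half-hour observations to a common geometry across the day.

Kernel closed forms follow the standard semi-empirical kernel-driven
literature (Roujean/Wanner family); the non-reciprocal Li-Sparse variant
is used with crown-shape defaults h/b = 2, b/r = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KernelParams",
    "BRDFFit",
    "InsufficientDataError",
    "ConditioningError",
    "ross_thick_kernel",
    "li_sparse_kernel",
    "fit_brdf",
    "hotspot_value",
]

#: Vertical extent of the goniometer scan (deg); hotspot evaluation beyond
#: this view zenith is an extrapolation and triggers a warning.
MAX_MEASURED_ZENITH = 60.0


class InsufficientDataError(ValueError):
    """Fewer rows / distinct geometries than the fit requires."""


class ConditioningError(ValueError):
    """Design matrix is rank-deficient or too ill-conditioned."""


@dataclass(frozen=True)
class KernelParams:
    """Li-Sparse crown-shape ratios: relative height h/b, relative shape b/r."""

    h_over_b: float = 2.0
    b_over_r: float = 1.0

    def __post_init__(self) -> None:
        if self.h_over_b <= 0 or self.b_over_r <= 0:
            raise ValueError("kernel shape ratios must be positive")


@dataclass
class BRDFFit:
    """Least-squares LSRT fit of one index over one half-hour scan."""

    k_i: float
    k_g: float
    k_v: float
    residual_rms: float
    n_obs: int
    condition_number: float
    index_name: str = ""
    params: KernelParams = KernelParams()


def _angles(theta_v, theta_s, delta_phi):
    tv = np.deg2rad(np.asarray(theta_v, dtype=float))
    ts = np.deg2rad(np.asarray(theta_s, dtype=float))
    dp = np.deg2rad(np.asarray(delta_phi, dtype=float))
    return tv, ts, dp


def ross_thick_kernel(theta_v, theta_s, delta_phi):
    """Ross-Thick volumetric scattering kernel (angles in degrees).

    K_R = [((pi/2 - xi) cos xi + sin xi) / (cos theta_s + cos theta_v)] - pi/4
    with xi the phase angle between sun and view directions. Zero at
    nadir-overhead geometry and reciprocal in (theta_v, theta_s).
    """
    tv, ts, dp = _angles(theta_v, theta_s, delta_phi)
    cos_xi = np.cos(ts) * np.cos(tv) + np.sin(ts) * np.sin(tv) * np.cos(dp)
    cos_xi = np.clip(cos_xi, -1.0, 1.0)
    xi = np.arccos(cos_xi)
    return ((np.pi / 2 - xi) * cos_xi + np.sin(xi)) / (np.cos(ts) + np.cos(tv)) - (
        np.pi / 4
    )


def li_sparse_kernel(theta_v, theta_s, delta_phi, params: KernelParams = KernelParams()):
    """Li-Sparse geometric-optical kernel, non-reciprocal form (degrees).

    Crown shapes are mapped through the equivalent-angle transform
    theta' = arctan(b/r * tan theta); the crown-overlap term O uses the
    relative height h/b. Zero at nadir-overhead geometry with the default
    h/b = 2.
    """
    tv, ts, dp = _angles(theta_v, theta_s, delta_phi)
    tv_p = np.arctan(params.b_over_r * np.tan(tv))
    ts_p = np.arctan(params.b_over_r * np.tan(ts))
    cos_xi_p = np.cos(ts_p) * np.cos(tv_p) + np.sin(ts_p) * np.sin(tv_p) * np.cos(dp)
    cos_xi_p = np.clip(cos_xi_p, -1.0, 1.0)
    sec_v = 1.0 / np.cos(tv_p)
    sec_s = 1.0 / np.cos(ts_p)
    d2 = (
        np.tan(ts_p) ** 2
        + np.tan(tv_p) ** 2
        - 2.0 * np.tan(ts_p) * np.tan(tv_p) * np.cos(dp)
    )
    d2 = np.maximum(d2, 0.0)
    cos_t = (
        params.h_over_b
        * np.sqrt(d2 + (np.tan(ts_p) * np.tan(tv_p) * np.sin(dp)) ** 2)
        / (sec_s + sec_v)
    )
    cos_t = np.clip(cos_t, -1.0, 1.0)
    t = np.arccos(cos_t)
    overlap = (1.0 / np.pi) * (t - np.sin(t) * cos_t) * (sec_s + sec_v)
    return overlap - sec_s - sec_v + 0.5 * (1.0 + cos_xi_p) * sec_v


def _design_matrix(df: pd.DataFrame, params: KernelParams) -> np.ndarray:
    dphi = _relative_azimuth(df)
    k_l = li_sparse_kernel(
        df["view_zenith_deg"], df["solar_zenith_deg"], dphi, params
    )
    k_r = ross_thick_kernel(df["view_zenith_deg"], df["solar_zenith_deg"], dphi)
    return np.column_stack([np.ones(len(df)), np.asarray(k_l), np.asarray(k_r)])


def _relative_azimuth(df: pd.DataFrame) -> np.ndarray:
    d = np.abs(df["view_azimuth_deg"].to_numpy() - df["solar_azimuth_deg"].to_numpy())
    d = d % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def fit_brdf(
    indices: pd.DataFrame,
    which: str,
    params: KernelParams = KernelParams(),
    max_condition: float = 1e6,
) -> BRDFFit:
    """OLS inversion of the LSRT model for one index over one scan.

    ``indices`` is an angular index set (one row per direction) with
    geometry columns, the index column named by ``which`` ('pri' or 'sif'),
    and optionally ``qc_flags`` (flagged rows are excluded).
    """
    df = indices
    if "qc_flags" in df.columns:
        # negative-SIF flags (bit 2) are retained so the fit sees unbiased
        # noise; reflectance-range flags (bit 1) are excluded
        df = df[(df["qc_flags"].to_numpy(dtype=int) & 1) == 0]
    df = df.dropna(subset=[which])
    if len(df) < 3:
        raise InsufficientDataError(f"need >= 3 usable rows, have {len(df)}")
    geo = df[["view_zenith_deg", "view_azimuth_deg", "solar_zenith_deg",
              "solar_azimuth_deg"]].drop_duplicates()
    if len(geo) < 3:
        raise InsufficientDataError("need >= 3 distinct geometries")
    x = _design_matrix(df, params)
    y = df[which].to_numpy(dtype=float)
    cond = float(np.linalg.cond(x))
    if not np.isfinite(cond):
        raise ConditioningError("rank-deficient kernel design matrix")
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < 3:
        raise ConditioningError("rank-deficient kernel design matrix")
    resid = y - x @ coef
    return BRDFFit(
        k_i=float(coef[0]),
        k_g=float(coef[1]),
        k_v=float(coef[2]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_obs=len(df),
        condition_number=cond,
        index_name=which,
        params=params,
    )


def hotspot_value(fit: BRDFFit, theta_s: float, params: KernelParams | None = None) -> float:
    """Evaluate the fitted BRDF at the hotspot (theta_v = theta_s, dphi = 0).

    At the sun-view coincident geometry shadows are hidden from the sensor,
    so this value normalizes the half-hour observation to a common,
    illumination-defined geometry. Warns when the solar zenith exceeds the
    measured vertical range (extrapolation beyond the scanned hemisphere).
    """
    p = params if params is not None else fit.params
    if theta_s > MAX_MEASURED_ZENITH:
        warnings.warn(
            f"hotspot at theta_s={theta_s:.1f} deg extrapolates beyond the "
            f"{MAX_MEASURED_ZENITH:.0f} deg measured vertical range",
            stacklevel=2,
        )
    k_l = float(li_sparse_kernel(theta_s, theta_s, 0.0, p))
    k_r = float(ross_thick_kernel(theta_s, theta_s, 0.0))
    return fit.k_i + fit.k_g * k_l + fit.k_v * k_r
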