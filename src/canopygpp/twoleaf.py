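"""Two-leaf (sunlit/shaded) decomposition of angular PRI/SIF.

The observed canopy signal at each view angle mixes sunlit leaves, shaded
leaves and background in proportions that change with geometry. Following
the two-leaf approach, each half-hour angular index set is decomposed as

    rho_obs(angle) = P_T(angle) * rho_sun + P_S(angle) * rho_sh

where P_T is the sunlit-leaf fraction (ratio of observed canopy
reflectance to leaf reflectance at 670 nm), P_VG = exp(-0.5 Omega LAI /
cos theta_v) the gap/background fraction from Beer's-law gap probability
with clumping index Omega, and P_S = 1 - P_T - P_VG the shaded fraction.
Least squares over the rotation cycle yields the component values
(rho_sun, rho_sh), and the total-canopy index weights them by the sunlit
and shaded LAI fractions: rho_tot = (L_sun/LAI) rho_sun + (L_sh/LAI) rho_sh
with L_sun = 2 cos theta_s (1 - exp(-0.5 Omega LAI / cos theta_s)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TwoLeafConfig",
    "ComponentFractions",
    "TwoLeafResult",
    "GeometryError",
    "FractionError",
    "background_fraction",
    "sunlit_fraction",
    "shaded_fraction",
    "sunlit_shaded_lai",
    "solve_sun_shade",
    "total_canopy_index",
    "decompose_scan",
    "interpolate_lai",
]


class GeometryError(ValueError):
    """Zenith angle at or beyond 90 degrees."""


class FractionError(ValueError):
    """Component fractions violate closure constraints."""


@dataclass(frozen=True)
class TwoLeafConfig:
    """Parameters of the two-leaf decomposition.

    omega
        Leaf clumping index correcting the gap-fraction formula for
        non-random foliage dispersion; 0.9 for a rice canopy.
    lambda_pt
        Wavelength (nm) at which the sunlit fraction is taken as the ratio
        of canopy to leaf reflectance; 670 nm (red absorption maximum).
    leaf_reflectance_670
        Leaf-level reflectance at ``lambda_pt``, supplied externally (e.g.
        from a PROSPECT run for rice or from literature).
    clamp_negative_sif
        Clamp negative SIF component solutions to 0 (with a QC note);
        PRI components are never clamped (PRI is naturally negative).
    """

    omega: float = 0.9
    lambda_pt: float = 670.0
    leaf_reflectance_670: float = 0.05
    clamp_negative_sif: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.omega <= 1.0):
            raise ValueError("clumping index must lie in (0, 1]")
        if not (0.0 < self.leaf_reflectance_670 < 1.0):
            raise ValueError("leaf reflectance must lie in (0, 1)")


@dataclass(frozen=True)
class ComponentFractions:
    """Sunlit / shaded / background proportions seen at one view angle."""

    p_t: float
    p_s: float
    p_vg: float
    theta_v: float

    def __post_init__(self) -> None:
        for v in (self.p_t, self.p_s, self.p_vg):
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise FractionError(f"fraction {v} outside [0, 1]")
        if abs(self.p_t + self.p_s + self.p_vg - 1.0) > 1e-9:
            raise FractionError("fractions must close to 1")


@dataclass
class TwoLeafResult:
    """Component solution and LAI-weighted canopy total for one index."""

    rho_sun: float
    rho_sh: float
    l_sun: float
    l_sh: float
    rho_tot: float
    n_obs: int
    residual_rms: float
    condition_number: float
    index_name: str = ""
    clamped: bool = False


def background_fraction(lai: float, theta_v: float, cfg: TwoLeafConfig) -> float:
    """Gap (background) fraction P_VG = exp(-0.5 Omega LAI / cos theta_v)."""
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    if not (0.0 <= theta_v < 90.0):
        raise GeometryError("view zenith must lie in [0, 90) degrees")
    return float(np.exp(-0.5 * cfg.omega * lai / np.cos(np.deg2rad(theta_v))))


def sunlit_fraction(canopy_refl_670: float, cfg: TwoLeafConfig, p_vg: float) -> float:
    """Sunlit-leaf fraction P_T = R_canopy(670) / R_leaf(670).

    Clamped into [0, 1 - P_VG] so the closure P_T + P_S + P_VG = 1 can hold
    with P_S >= 0; clamping events are logged.
    """
    if cfg.leaf_reflectance_670 <= 0:
        raise ValueError("leaf reflectance must be positive")
    p_t = canopy_refl_670 / cfg.leaf_reflectance_670
    hi = 1.0 - p_vg
    if p_t < 0.0 or p_t > hi:
        logger.debug("P_T=%.4f clamped into [0, %.4f]", p_t, hi)
        p_t = min(max(p_t, 0.0), hi)
    return float(p_t)


def shaded_fraction(p_t: float, p_vg: float) -> float:
    """Shaded-leaf fraction P_S = 1 - P_T - P_VG."""
    if p_t + p_vg > 1.0 + 1e-12:
        raise FractionError("P_T + P_VG exceeds 1")
    return max(1.0 - p_t - p_vg, 0.0)


def sunlit_shaded_lai(
    lai: float, theta_s: float, cfg: TwoLeafConfig
) -> tuple[float, float]:
    """Partition LAI into sunlit and shaded parts at solar zenith theta_s.

    L_sun = 2 cos theta_s (1 - exp(-0.5 Omega LAI / cos theta_s));
    L_sh = LAI - L_sun. The identity L_sun + L_sh = LAI holds exactly.
    """
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    if not (0.0 <= theta_s < 90.0):
        raise GeometryError("solar zenith must lie in [0, 90) degrees")
    cos_t = np.cos(np.deg2rad(theta_s))
    l_sun = float(2.0 * cos_t * (1.0 - np.exp(-0.5 * cfg.omega * lai / cos_t)))
    return l_sun, lai - l_sun


def interpolate_lai(survey: pd.DataFrame, doys) -> pd.Series:
    """Linearly interpolate sparse (~7-day) LAI measurements to given days.

    ``survey`` carries columns ``doy`` and ``lai``; values outside the
    surveyed range are held at the nearest measurement.
    """
    s = survey.sort_values("doy")
    out = np.interp(np.asarray(doys, dtype=float), s["doy"], s["lai"])
    return pd.Series(out, index=pd.Index(doys, name="doy"), name="lai")


def fractions_for_scan(
    indices: pd.DataFrame, lai: float, cfg: TwoLeafConfig
) -> list[ComponentFractions]:
    """Per-angle component fractions from the scan's 670 nm reflectance."""
    out = []
    for theta_v, r670 in zip(
        indices["view_zenith_deg"].to_numpy(), indices["refl_670"].to_numpy()
    ):
        p_vg = background_fraction(lai, float(theta_v), cfg)
        p_t = sunlit_fraction(float(r670), cfg, p_vg)
        p_s = shaded_fraction(p_t, p_vg)
        out.append(ComponentFractions(p_t=p_t, p_s=p_s, p_vg=p_vg, theta_v=float(theta_v)))
    return out


def solve_sun_shade(
    indices: pd.DataFrame,
    fractions: list[ComponentFractions],
    which: str,
) -> tuple[float, float, dict]:
    """Least-squares solve of rho_obs = P_T rho_sun + P_S rho_sh (no intercept).

    Returns (rho_sun, rho_sh, diagnostics) with diagnostics carrying
    residual_rms, condition_number and n_obs.
    """
    if len(indices) != len(fractions):
        raise ValueError("one fraction set per index row required")
    if len(indices) < 2:
        raise ValueError("need >= 2 rows to separate sunlit and shaded components")
    x = np.array([[f.p_t, f.p_s] for f in fractions], dtype=float)
    y = indices[which].to_numpy(dtype=float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    cond = float(np.linalg.cond(x))
    if not np.isfinite(cond) or cond > 1e10:
        raise FractionError(
            "sunlit/shaded fractions are collinear across angles; "
            "components not separable"
        )
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < 2:
        raise FractionError("rank-deficient sunlit/shaded design")
    resid = y - x @ coef
    diagnostics = {
        "residual_rms": float(np.sqrt(np.mean(resid**2))),
        "condition_number": cond,
        "n_obs": int(len(y)),
    }
    return float(coef[0]), float(coef[1]), diagnostics


def total_canopy_index(
    rho_sun: float, rho_sh: float, l_sun: float, l_sh: float
) -> float:
    """LAI-weighted canopy total rho_tot = (L_sun/LAI) rho_sun + (L_sh/LAI) rho_sh."""
    lai = l_sun + l_sh
    if lai <= 0:
        raise ValueError("total LAI must be positive to form the canopy total")
    return (l_sun / lai) * rho_sun + (l_sh / lai) * rho_sh


def decompose_scan(
    indices: pd.DataFrame,
    lai: float,
    theta_s: float,
    which: str,
    cfg: TwoLeafConfig = TwoLeafConfig(),
) -> TwoLeafResult:
    """Full two-leaf decomposition of one half-hour angular index set.

    ``theta_s`` is the solar zenith at the scan midpoint, used for the
    sunlit/shaded LAI partition (the per-angle background fraction uses
    each record's view zenith).
    """
    df = indices
    if "qc_flags" in df.columns:
        df = df[(df["qc_flags"].to_numpy(dtype=int) & 1) == 0]
    fracs = fractions_for_scan(df, lai, cfg)
    rho_sun, rho_sh, diag = solve_sun_shade(df, fracs, which)
    clamped = False
    if which == "sif" and cfg.clamp_negative_sif:
        if rho_sun < 0 or rho_sh < 0:
            clamped = True
            rho_sun = max(rho_sun, 0.0)
            rho_sh = max(rho_sh, 0.0)
    l_sun, l_sh = sunlit_shaded_lai(lai, theta_s, cfg)
    rho_tot = total_canopy_index(rho_sun, rho_sh, l_sun, l_sh)
    return TwoLeafResult(
        rho_sun=rho_sun,
        rho_sh=rho_sh,
        l_sun=l_sun,
        l_sh=l_sh,
        rho_tot=rho_tot,
        n_obs=diag["n_obs"],
        residual_rms=diag["residual_rms"],
        condition_number=diag["condition_number"],
        index_name=which,
        clamped=clamped,
    )
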