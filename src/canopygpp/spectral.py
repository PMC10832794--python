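"""Per-angle spectral retrieval: reflectance calibration, PRI, and 3FLD SIF.

Raw inputs are paired reflected-radiance / downwelling-irradiance spectra
(350-800 nm) recorded for each view direction of a half-hour angular scan.
This module converts each pair into canopy reflectance via a whiteboard
(standard reflectance panel) correction, computes the photochemical
reflectance index PRI = (R531 - R570)/(R531 + R570), and retrieves
solar-induced chlorophyll fluorescence with the three-band Fraunhofer Line
Discrimination (3FLD) algorithm inside the O2-A absorption feature near
762 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "WhiteboardCalibration",
    "FLDBandConfig",
    "PRIBandConfig",
    "ViewGeometry",
    "AngularScan",
    "GridError",
    "CalibrationError",
    "UndefinedIndexError",
    "NoDipError",
    "EmptyScanError",
    "calibrate_reflectance",
    "compute_pri",
    "fld_weights",
    "retrieve_sif_3fld",
    "process_angular_scan",
    "QC_OK",
    "QC_REFLECTANCE_RANGE",
    "QC_NEGATIVE_SIF",
]

# QC bit flags carried per directional record
QC_OK = 0
QC_REFLECTANCE_RANGE = 1  # reflectance outside [0, 1] in a required band
QC_NEGATIVE_SIF = 2  # negative 3FLD retrieval (kept, not clipped)

#: Wavelength-grid matching tolerance (nm). Coarser mismatch is an error,
#: not an interpolation.
GRID_TOL_NM = 0.5


class GridError(ValueError):
    """Wavelength grids of paired spectra do not match within tolerance."""


class CalibrationError(ValueError):
    """Nonpositive downwelling or whiteboard value."""


class UndefinedIndexError(ValueError):
    """Index denominator is zero (e.g. R531 + R570 = 0)."""


class NoDipError(ValueError):
    """No absorption contrast between in-band and out-band irradiance."""


class EmptyScanError(ValueError):
    """Angular scan contains no directional records."""


@dataclass
class Spectrum:
    """A sampled spectrum on a strictly increasing wavelength grid.

    ``kind`` distinguishes reflected radiance (W m-2 um-1 sr-1),
    downwelling irradiance (W m-2 um-1) and dimensionless reflectance.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: Literal["reflected", "downwelling", "reflectance"]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")

    def band_mean(self, center: float, half_width: float) -> float:
        """Mean value of all samples within ``center +/- half_width`` nm."""
        mask = np.abs(self.wavelengths - center) <= half_width
        if not mask.any():
            # fall back to the nearest sample within the grid-matching tolerance
            i = int(np.argmin(np.abs(self.wavelengths - center)))
            if abs(self.wavelengths[i] - center) > GRID_TOL_NM:
                raise GridError(
                    f"no samples within {half_width} nm of {center} nm "
                    f"(nearest at {self.wavelengths[i]:.1f} nm)"
                )
            mask = np.zeros_like(self.wavelengths, dtype=bool)
            mask[i] = True
        return float(self.values[mask].mean())


@dataclass
class WhiteboardCalibration:
    """Reference-panel spectra L' (reflected) and E' (downwelling).

    Recorded over a standard whiteboard at (nominally) the same moment as
    the canopy measurement; used in the product-form reflectance correction
    R = (L * L') / (E * E').
    """

    wavelengths: np.ndarray
    board_reflected: np.ndarray
    board_downwelling: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.board_reflected = np.asarray(self.board_reflected, dtype=float)
        self.board_downwelling = np.asarray(self.board_downwelling, dtype=float)
        if np.any(self.board_reflected <= 0) or np.any(self.board_downwelling <= 0):
            raise CalibrationError("whiteboard spectra must be strictly positive")


@dataclass(frozen=True)
class FLDBandConfig:
    """Band placement for the 3FLD retrieval around the O2-A feature.

    Defaults: 762 nm in-band with 758/769 nm outer bands.
    """

    lambda_in: float = 762.0
    lambda_left: float = 758.0
    lambda_right: float = 769.0
    bandwidth: float = 1.0  # half-width (nm) for band averaging
    min_contrast: float = 0.02  # minimum fractional in-band absorption

    def __post_init__(self) -> None:
        if not (self.lambda_left < self.lambda_in < self.lambda_right):
            raise ValueError("band ordering must satisfy left < in < right")


@dataclass(frozen=True)
class PRIBandConfig:
    """Band centers for PRI (xanthophyll 531 nm vs reference 570 nm)."""

    lambda_531: float = 531.0
    lambda_570: float = 570.0
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        for lam in (self.lambda_531, self.lambda_570):
            if not (350.0 <= lam <= 800.0):
                raise ValueError("PRI bands must lie inside the 350-800 nm range")


@dataclass(frozen=True)
class ViewGeometry:
    """One sun-sensor configuration, angles in degrees."""

    theta_v: float
    phi_v: float
    theta_s: float
    phi_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_v < 90.0 and 0.0 <= self.theta_s < 90.0):
            raise ValueError("zenith angles must lie in [0, 90) degrees")

    @property
    def delta_phi(self) -> float:
        """Relative azimuth normalized to [0, 180] degrees."""
        d = abs(self.phi_v - self.phi_s) % 360.0
        return 360.0 - d if d > 180.0 else d


@dataclass
class AngularScan:
    """One half-hour rotation cycle of directional spectra.

    Each record pairs a :class:`ViewGeometry` with a reflected-radiance
    spectrum; ``downwelling`` holds the synchronous irradiance spectrum for
    each record (a single shared spectrum may be broadcast).
    """

    timestamp: pd.Timestamp
    geometries: list[ViewGeometry]
    reflected: list[Spectrum]
    downwelling: list[Spectrum]

    def __post_init__(self) -> None:
        n = len(self.geometries)
        if len(self.reflected) != n:
            raise ValueError("one reflected spectrum per geometry required")
        if len(self.downwelling) == 1 and n > 1:
            self.downwelling = list(self.downwelling) * n
        if len(self.downwelling) != n:
            raise ValueError("one downwelling spectrum per geometry required")

    def __len__(self) -> int:
        return len(self.geometries)


def _check_grids(*spectra_wl: np.ndarray) -> None:
    ref = spectra_wl[0]
    for wl in spectra_wl[1:]:
        if wl.shape != ref.shape or np.any(np.abs(wl - ref) > GRID_TOL_NM):
            raise GridError("wavelength grids differ by more than 0.5 nm")


def calibrate_reflectance(
    reflected: Spectrum,
    downwelling: Spectrum,
    cal: WhiteboardCalibration,
) -> tuple[Spectrum, np.ndarray]:
    """Whiteboard reflectance correction R = (L * L') / (E * E').

    Returns the reflectance spectrum and a boolean QC mask flagging samples
    outside [0, 1] (flagged, never clipped).
    """
    _check_grids(reflected.wavelengths, downwelling.wavelengths, cal.wavelengths)
    if np.any(downwelling.values <= 0):
        raise CalibrationError("downwelling irradiance must be strictly positive")
    r = (reflected.values * cal.board_reflected) / (
        downwelling.values * cal.board_downwelling
    )
    qc_mask = (r < 0.0) | (r > 1.0)
    return Spectrum(reflected.wavelengths, r, kind="reflectance"), qc_mask


def compute_pri(reflectance: Spectrum, cfg: PRIBandConfig = PRIBandConfig()) -> float:
    """PRI = (R531 - R570) / (R531 + R570) from band-mean reflectances."""
    if reflectance.kind != "reflectance":
        raise ValueError("compute_pri requires a reflectance spectrum")
    r531 = reflectance.band_mean(cfg.lambda_531, cfg.bandwidth)
    r570 = reflectance.band_mean(cfg.lambda_570, cfg.bandwidth)
    denom = r531 + r570
    if denom == 0.0:
        raise UndefinedIndexError("R531 + R570 = 0; PRI undefined")
    return (r531 - r570) / denom


def fld_weights(cfg: FLDBandConfig) -> tuple[float, float]:
    """Outer-band weights for 3FLD.

    w_left = (lambda_right - lambda_in) / (lambda_right - lambda_left) and
    w_right = 1 - w_left, so the weighted outer-band wavelength equals the
    in-band wavelength.
    """
    span = cfg.lambda_right - cfg.lambda_left
    if span == 0.0:
        raise ValueError("degenerate band: lambda_right == lambda_left")
    w_left = (cfg.lambda_right - cfg.lambda_in) / span
    w_right = (cfg.lambda_in - cfg.lambda_left) / span
    return w_left, w_right


def retrieve_sif_3fld(
    reflected: Spectrum,
    downwelling: Spectrum,
    cfg: FLDBandConfig = FLDBandConfig(),
) -> float:
    """3FLD fluorescence retrieval inside an absorption line.

    SIF = (E_out * L_in - E_in * L_out) / (E_out - E_in), where the out-band
    radiance/irradiance are the weighted averages of the left and right
    shoulder bands. Exact when true reflectance and fluorescence are
    spectrally flat over the three bands. Negative retrievals are returned
    as-is (the caller flags them).
    """
    _check_grids(reflected.wavelengths, downwelling.wavelengths)
    w_left, w_right = fld_weights(cfg)
    bw = cfg.bandwidth
    e_in = downwelling.band_mean(cfg.lambda_in, bw)
    l_in = reflected.band_mean(cfg.lambda_in, bw)
    e_out = w_left * downwelling.band_mean(cfg.lambda_left, bw) + (
        w_right * downwelling.band_mean(cfg.lambda_right, bw)
    )
    l_out = w_left * reflected.band_mean(cfg.lambda_left, bw) + (
        w_right * reflected.band_mean(cfg.lambda_right, bw)
    )
    if abs(e_out - e_in) < cfg.min_contrast * abs(e_out):
        raise NoDipError(
            "insufficient absorption contrast at the dark line "
            f"(|E_out - E_in| / E_out < {cfg.min_contrast})"
        )
    return (e_out * l_in - e_in * l_out) / (e_out - e_in)


def process_angular_scan(
    scan: AngularScan,
    cal: WhiteboardCalibration,
    pri_cfg: PRIBandConfig = PRIBandConfig(),
    fld_cfg: FLDBandConfig = FLDBandConfig(),
    refl_670_bandwidth: float = 1.0,
) -> pd.DataFrame:
    """Apply calibration, PRI and 3FLD to every directional record.

    Returns one row per record: geometry columns, ``pri``, ``sif``,
    ``refl_670`` (canopy reflectance at 670 nm, used downstream for the
    sunlit-leaf fraction) and a ``qc_flags`` bitmask. Row count equals the
    scan length.
    """
    if len(scan) == 0:
        raise EmptyScanError("angular scan has no directional records")
    rows = []
    for geom, refl, down in zip(scan.geometries, scan.reflected, scan.downwelling):
        reflectance, qc_mask = calibrate_reflectance(refl, down, cal)
        qc = QC_OK
        # restrict the range check to the bands actually used
        for center, bw in (
            (pri_cfg.lambda_531, pri_cfg.bandwidth),
            (pri_cfg.lambda_570, pri_cfg.bandwidth),
            (670.0, refl_670_bandwidth),
        ):
            in_band = np.abs(reflectance.wavelengths - center) <= bw
            if qc_mask[in_band].any():
                qc |= QC_REFLECTANCE_RANGE
        pri = compute_pri(reflectance, pri_cfg)
        sif = retrieve_sif_3fld(refl, down, fld_cfg)
        if sif < 0:
            qc |= QC_NEGATIVE_SIF
        rows.append(
            {
                "timestamp": scan.timestamp,
                "view_zenith_deg": geom.theta_v,
                "view_azimuth_deg": geom.phi_v,
                "solar_zenith_deg": geom.theta_s,
                "solar_azimuth_deg": geom.phi_s,
                "pri": pri,
                "sif": sif,
                "refl_670": reflectance.band_mean(670.0, refl_670_bandwidth),
                "qc_flags": qc,
            }
        )
    return pd.DataFrame(rows)
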