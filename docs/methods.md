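# Methods

This note documents the models implemented in `canopygpp`, their
assumptions, the parameter choices that matter, and what the synthetic
validation does and does not demonstrate.

## Spectral retrieval

**Reflectance.** Canopy reflectance is recovered from paired
reflected-radiance / downwelling-irradiance spectra by whiteboard
correction in the product form R = (L·L′)/(E·E′), with L′, E′ the
reference-panel spectra. The package implements this form literally;
the common quotient form R = (L/E)·(E′/L′) differs only by the panel
calibration convention, and the synthetic generator uses a panel with
L′ = E′ so both forms coincide there. Reflectance outside [0, 1] is
flagged in a QC mask, never clipped.

**PRI.** PRI = (R531 − R570)/(R531 + R570). Band values are means of
all grid samples within ±bandwidth of the band center; the default
bandwidth is 1 nm, configurable because the appropriate averaging width
depends on the spectrometer's sampling interval. Wavelength grids of
paired spectra must agree to 0.5 nm (nearest-neighbor); coarser
mismatch is an error rather than a silent interpolation.

**3FLD SIF.** The three-band Fraunhofer Line Discrimination retrieval
uses the O₂-A feature: in-band 762 nm, shoulders 758 and 769 nm with
weights w_left = (λ_right − λ_in)/(λ_right − λ_left), w_right = 1 −
w_left, and

SIF = (E_out·L_in − E_in·L_out)/(E_out − E_in).

The retrieval is algebraically exact when true reflectance and
fluorescence are spectrally constant over the three bands — this is the
basis of the exactness test. Retrievals with in-band/out-band
irradiance contrast below 2 % are rejected as "no dip" (the retrieval
is unstable there); negative retrievals are kept with a QC flag so the
downstream BRDF fit sees unbiased noise, with clipping available as a
config option. Irradiance and radiance are treated on a common radiance
scale (the sr⁻¹ factor cancels in the ratio structure of the 3FLD
equation).

## BRDF hotspot normalization

Each half-hour angular index set is fitted by ordinary least squares to
the kernel-driven superposition ρ = k_i + k_g·K_L + k_v·K_R. The kernel
closed forms are the standard semi-empirical ones: Ross-Thick
volumetric,

K_R = [((π/2 − ξ)cos ξ + sin ξ)/(cos θ_s + cos θ_v)] − π/4,
cos ξ = cos θ_s cos θ_v + sin θ_s sin θ_v cos Δφ,

and the non-reciprocal Li-Sparse geometric kernel with equivalent-angle
transform θ′ = arctan(b/r·tan θ) and crown-overlap term driven by h/b.
Defaults h/b = 2, b/r = 1 are the conventional crop-canopy choices;
both are configurable. One fit per half-hour group per index (PRI,
SIF). The hotspot value is the fitted surface at exact sun–view
coincidence (θ_v = θ_s, Δφ = 0) with no hotspot-broadening term; a
warning is emitted when θ_s exceeds the 60° scanned vertical range,
since the evaluation is then an extrapolation. Fits with fewer than 30
usable rows or design condition number above 10⁶ are flagged
low-quality (both thresholds configurable); no background term beyond
k_i is included, i.e. the background is assumed angularly constant
within a half-hour.

## Two-leaf decomposition

The observed index at each angle is modeled as a mixture of sunlit and
shaded leaf components, ρ_obs = P_T·ρ_sun + P_S·ρ_sh, solved by
unweighted least squares (no intercept) over the rotation cycle. The
angle-dependent fractions are

- P_VG = exp(−0.5·Ω·LAI/cos θ_v), the gap/background fraction from
  Beer's-law gap probability with clumping index Ω = 0.9 (rice canopy);
- P_T = R_canopy(670 nm)/R_leaf(670 nm), using the per-angle canopy
  reflectance from the same scan, clamped into [0, 1 − P_VG] (clamping
  logged); leaf reflectance at 670 nm is a config scalar (default 0.05,
  appropriate for healthy rice leaves from radiative-transfer model
  output or literature) — running a leaf radiative-transfer model is
  out of scope since only this one number is needed;
- P_S = 1 − P_T − P_VG, so fraction closure holds by construction.

The background fraction uses the *view* zenith (what the sensor sees);
the sunlit-LAI partition L_sun = 2 cos θ (1 − exp(−0.5·Ω·LAI/cos θ))
uses the *solar* zenith at the scan midpoint (what the sun
illuminates), following the two-leaf literature's usage of the two
angles. L_sh = LAI − L_sun exactly, and the canopy total
ρ_tot = (L_sun/LAI)·ρ_sun + (L_sh/LAI)·ρ_sh is a convex combination of
the component values. Negative SIF component solutions are clamped to
0 with a QC flag (configurable); PRI components are never clamped since
PRI is naturally negative. LAI between the ~7-day field measurements is
linearly interpolated to daily values.

## Flux processing

Half-hourly NEE (mg CO₂ m⁻² s⁻¹; negative = uptake) is screened with
four rules, each removal tagged: (a) out of instrument range
(plausibility window |NEE| ≤ 3 mg m⁻² s⁻¹ by default, since no
published numeric device range exists), (b) negative NEE at night, (c)
within 1 h before/after a rainfall event, (d) night-time u* below
0.13 m s⁻¹. Night is defined as PAR < 5 µmol m⁻² s⁻¹ (configurable) —
operationally "no photosynthetically active radiation". Rule precedence
for reporting is a > b > c > d when several apply.

Night-time NEE is ecosystem respiration; screened nights are fitted by
untransformed nonlinear least squares to the Van't Hoff response
R_e = R_e,ref·exp(B(T − T_ref)), T_ref = 25 °C, requiring ≥ 10 nights
spanning ≥ 5 °C so B is identifiable. Daytime gaps are filled by the
mean diurnal course (same half-hour slot, ±7-day window); night gaps by
the fitted respiration curve at the record's temperature. Partitioning
uses GPP = R_e − NEE with daytime R_e from the fitted curve; at night
the (gap-filled) NEE itself is taken as R_e, which makes night GPP
exactly zero and the identity GPP + NEE − R_e = 0 hold on every
processed record.

## GPP models and evaluation

Matched half-hourly samples (09:00–15:00) pair flux GPP with the four
index variants of the same half-hour. Flux arithmetic is done in
mg CO₂ m⁻² s⁻¹ (the scale of the respiration parameters); the
regression stage converts GPP to µmol CO₂ m⁻² s⁻¹ (× 22.722), the
scale on which the model coefficients are reported. The split into
modeling and validation sets is by day of year (default validation
DOYs 224, 251, 271 — tasseling, filling and maturity stages — giving
286/39 of the 325 groups). Six OLS models with intercept are fitted:
{PRI, SIF, PRI+SIF} × {hs, tot}. Reported metrics: in-sample R², RMSE
(1/n convention) and regression F on the modeling set; out-of-sample
R², RMSE and RPD = SD/RMSE on the validation set, with SD the sample
(n−1) standard deviation of observed validation GPP (the chemometrics
RPD convention). A perfect fit yields an infinite RPD, flagged rather
than raised. The stratified analysis bins samples by LAI {<6, 6–7, >7},
T {<25, 25–30, >30} °C and VPD {<2, 2–3, >3} kPa and reports the
univariate R² of GPP on each index per bin, with significance stars
from the regression F test at p < 0.05 (*) and p < 0.01 (**); no
multiple-testing correction is applied across strata. Daily aggregation
reports per-day means and standard errors, with days classed cloudy
when daily mean PAR < 1,000 µmol m⁻² s⁻¹.

## Synthetic campaign generator

The generator emulates the study conditions: 25 observation days
(DOY 215–277, including the three validation days), 13 half-hour groups
per day 09:00–15:00, an angular grid of 31 azimuths (−150°…+150°) × 7
zeniths (0°…60°) at 10° steps repeated ~7× with 1.5° jitter (≈1,519
records per group), LAI rising from 5.5 to a peak of 7.7 at DOY 224
then falling to 3.0, sampled every 7 days as the field survey. Solar
geometry uses a low-precision ephemeris (declination sine
approximation + hour angle) at 32.43° N, 116.78° E; the pipeline itself
takes angles as data, so ephemeris accuracy is immaterial.

Because the LSRT superposition and the two-leaf mixture cannot both be
exactly true of one angular field, the generator offers three forward
modes: `twoleaf` (the field is an exact P_T/P_S mixture; default),
`brdf` (exact LSRT field with truth kernel coefficients), and `mixed`
(their average, for qualitative end-to-end checks). Each inversion is
tested against its own exact forward model. Full spectra (451-point
1-nm grid, Gaussian O₂-A dip of fractional depth 0.6 and σ = 1 nm at
762 nm, piecewise reflectance flat within ±2 nm of every band in use,
fluorescence constant above 740 nm) are generated per scan for the
spectral-stage round trip; campaign-scale runs generate index-level
angular sets directly, since the ~450 million spectral samples of a
full 325-group spectral campaign would add nothing to what the
per-scan round trip already verifies.

Index magnitudes follow field-plausible scales (PRI ≈ −0.11…−0.02,
SIF ≈ 0–0.25 W m⁻² µm⁻¹ sr⁻¹) with per-angle noise σ_PRI = 0.002,
σ_SIF = 0.004 and small per-group component jitter. Flux days carry
sinusoidal temperature (20–33 °C across the season), VPD from saturated
vapor pressure with a diurnal humidity cycle, PAR shaped by solar
geometry with ~30 % of days cloudy (clearness 0.2–0.42), respiration
with R_e,ref = 0.22 mg m⁻² s⁻¹ and B = 0.1235 °C⁻¹, NEE noise
σ = 0.02 mg m⁻² s⁻¹, and injected artifacts (30 % of night half-hours
with low u*, 15 % of days with a rain event, 1 % range spikes, 2 %
missing slots) so every screening rule is exercised. Campaign GPP for
the observation groups is coupled linearly to the truth totals,
GPP = 118.06·SIF_tot − 130.47·PRI_tot − 5.29 (µmol m⁻² s⁻¹), giving the
end-to-end regression a known target; outside the observation window a
saturating PAR light response scaled by LAI is used.

## Numerical choices

- All angular interfaces are in degrees; conversion to radians is
  internal. Relative azimuth is normalized to [0°, 180°].
- Linear solves use `numpy.linalg.lstsq`; the two-leaf solve rejects
  designs with condition number > 10¹⁰ (collinear fractions). The
  Van't Hoff fit uses Levenberg–Marquardt (`scipy.optimize.curve_fit`)
  initialized at the night-mean respiration and B = 0.1.
- Degenerate inputs fail loud and specific: mismatched wavelength
  grids, zero PRI denominator, insufficient absorption contrast, empty
  scans, unsorted flux timestamps, empty split sides, single-row
  validation sets. Sparse stratification bins report undefined R²
  rather than raising.
- The L_sun + L_sh = LAI and P_T + P_S + P_VG = 1 closures are exact by
  construction (one floating-point rounding at re-addition).

## What the synthetic validation shows — and does not

Passing recovery tests demonstrates that each inversion is implemented
correctly against its own forward model at the campaign's noise levels,
and that the pipeline's bookkeeping (splits, merges, units, QC) is
sound. It does not demonstrate that the forward models describe real
rice canopies: the generator has no directional background reflectance,
no hotspot broadening, no within-group physiological drift, no spectral
fluorescence shape, and its two-leaf and LSRT worlds are idealizations
that real angular fields only approximate. Coefficient recovery in the
end-to-end run is attenuated by a realistic feature: the pipeline
interpolates the 7-day LAI survey, which misses the true peak between
survey dates, so two-leaf totals carry a small errors-in-variables
bias (a few percent on the recovered coupling coefficients).

## Problem sizes

Default test and acceptance runs use the full 325-group campaign at the
index level (~494k angular rows), full per-scan spectra for the
spectral round trip (217–1,519 directions × 451 wavelengths), 200
replicates for BRDF noise-scaling checks and 300 for respiration-fit
bias checks; the complete suite runs in well under a minute of compute
plus ~15 s for the end-to-end campaign.
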