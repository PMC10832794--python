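# canopygpp

Estimating rice-canopy gross primary productivity (GPP) from multi-angle
hyperspectral observations of the photochemical reflectance index (PRI)
and solar-induced chlorophyll fluorescence (SIF), validated against
eddy-covariance flux measurements.

Canopy PRI and SIF observed from a single direction confound plant
physiology with viewing geometry: the sensor sees a different mixture of
sunlit leaves, shaded leaves and background at every angle. `canopygpp`
implements two complementary angular normalizations of half-hourly
multi-angle scans and uses them to build combined PRI+SIF regression
models of GPP:

1. **Hotspot normalization.** Each half-hour angular field ρ(θ_v, θ_s, Δφ)
   is fitted with the semi-empirical kernel-driven BRDF model

   ρ = k_i + k_g·K_L(θ_v, θ_s, Δφ; h/b, b/r) + k_v·K_R(θ_v, θ_s, Δφ)

   (Li-Sparse geometric + Ross-Thick volumetric kernels, "LSRT") and
   evaluated at the hotspot θ_v = θ_s, Δφ = 0, giving PRI_hs / SIF_hs.

2. **Two-leaf totals.** The same field is decomposed into sunlit and
   shaded leaf components via ρ_obs = P_T·ρ_sun + P_S·ρ_sh, where
   P_T = R_canopy(670)/R_leaf(670) is the sunlit fraction seen at each
   angle, P_VG = exp(−0.5·Ω·LAI/cos θ_v) the background/gap fraction
   (clumping index Ω = 0.9) and P_S = 1 − P_T − P_VG. LAI-weighted totals
   ρ_tot = (L_sun/LAI)·ρ_sun + (L_sh/LAI)·ρ_sh use the sunlit LAI
   L_sun = 2 cos θ_s (1 − exp(−0.5·Ω·LAI/cos θ_s)).

Upstream, per-angle indices come from whiteboard-calibrated reflectance
(R = L·L′/(E·E′)), PRI = (R531 − R570)/(R531 + R570), and 3-band
Fraunhofer Line Discrimination SIF retrieval in the O₂-A absorption
feature (762 nm in-band; 758/769 nm shoulders). Downstream, half-hourly
net ecosystem exchange is screened (instrument range, negative night
NEE, rain windows, low night-time friction velocity u* < 0.13 m s⁻¹),
gap-filled, and partitioned as GPP = R_e − NEE with the Van't Hoff
respiration model R_e = R_e,ref·exp(B(T − 25 °C)) fitted to non-rainy
nights. The final stage fits six OLS models (PRI / SIF / PRI+SIF, each
hotspot and total-canopy) on a day-of-year split and reports R², RMSE
and the relative prediction deviation RPD = SD/RMSE.

Because field campaigns of this kind are rarely public, the package
includes a first-class synthetic campaign generator (`canopygpp.synth`)
that produces every input — angular spectra with injected fluorescence,
LSRT- or two-leaf-consistent angular index fields, coupled flux series —
from a known `CampaignTruth`, so every inversion in the pipeline is
verifiable by parameter recovery.

## Worked example

Run the full synthetic campaign (25 days × 13 half-hour groups,
09:00–15:00, ≈1,500 angular samples per group) through every stage:

```bash
canopygpp run-all --seed 1 --out run1
```

which prints `pipeline complete: 325 matched samples` and writes the
stage tables into `run1/`. The respiration fit recovers the generator's
parameters (`re_ref = 0.2182` vs truth 0.22, `b = 0.1237` vs truth
0.1235), and `run1/validation.csv` contains:

```
      model        r2     rmse      rpd
     pri_hs  0.720267 2.259204 1.915441
    pri_tot  0.688560 2.383805 1.815321
     sif_hs  0.761256 2.087130 2.073359
    sif_tot  0.958049 0.874891 4.946182
 pri+sif_hs  0.753488 2.120814 2.040429
pri+sif_tot  0.981742 0.577186 7.497361
```

The PRI_tot+SIF_tot model performs best (validation R² = 0.98,
RPD = 7.5 on this noise level), and its fitted coefficients in
`run1/models.csv` — GPP = 115.5·SIF_tot − 130.5·PRI_tot − 5.18
(µmol CO₂ m⁻² s⁻¹) — recover the generator's coupling truth
GPP = 118.06·SIF_tot − 130.47·PRI_tot − 5.29. The total-canopy models
beat their hotspot counterparts because the generator couples GPP to the
whole-canopy signal, the same qualitative ordering expected when the
flux footprint integrates all canopy layers.

Individual stages are available as subcommands (`synth`, `spectra`,
`brdf`, `twoleaf`, `flux`, `models`) operating on plain CSV files, and
everything is importable as a library:

```python
from canopygpp import CampaignTruth, fit_brdf, hotspot_value
from canopygpp.synth import synth_angular_indices, group_truth

truth = CampaignTruth(seed=1)
idx = synth_angular_indices(truth, doy=224, slot=6, noise=False)
fit = fit_brdf(idx, "sif")
print(hotspot_value(fit, theta_s=group_truth(truth, 224, 6)["theta_s"]))
# 0.16664625322453436
```

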