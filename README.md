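# traitscape

Do plant and bird assemblages track the landscape they live in today, or
the landscape of decades ago? In intensifying agricultural regions,
landscape **simplification** (loss of compositional and configurational
heterogeneity) and habitat **fragmentation** (less habitat, more isolated
patches) filter species — but the community response can lag the change by
decades (*relaxation time*), leaving an unpaid *extinction debt*.

`traitscape` is a tested pipeline for detecting such signals with a
trait-based approach, for landscape and community ecologists. It:

1. quantifies landscape structure per 1 km × 1 km window at several map
   years — Shannon diversity H = −Σ p_c ln p_c (compositional
   heterogeneity), −ln(mean patch area) (configurational heterogeneity),
   grassland percentage and mean nearest edge-to-edge patch distance,
   hedgerow length and number of disconnected hedgerow networks;
2. computes community-weighted trait moments per window *k* and trait *j*,

       CWM_jk = Σᵢ P_ik · trait_ij,   CWV_jk = Σᵢ P_ik · trait_ij² − CWM_jk²

   with weights P_ik either presence/absence or occurrence rate;
3. tests non-randomness of CWV with two permutation null models — **NM1**
   redraws species identities from the regional pool (abundance-weighted,
   richness fixed), **NM2** shuffles occurrence-rate weights within each
   window — summarised by the rank-based effect size

       ES = ((N(null<obs) + N(null=obs)/2) / 1000 − 0.5) × 2  ∈ [−1, 1]

   (999 nulls; ES < 0 convergence, ES > 0 divergence), tested against 0
   across windows by Student's *t* or one-sample Wilcoxon;
4. regresses species richness and the gated CWV/CWM responses on each map
   year's predictors (full OLS; 4 predictors for plant groups, 6 for
   birds) and selects the best year(s) by **AICc** (ΔAICc < 2, normal
   residuals). A past year beating the current one is a time-lagged
   response.

Because such field data are rarely public, the package ships a first-class
synthetic-data module that emulates the whole study design — 20 windows,
3 map years with grassland→crop conversion and hedgerow loss, pools of
241/173/84 species with 5 traits each, realistic survey effort — with an
explicit, tunable ground-truth trait filter, so every stage can be
validated by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data with a known ground truth (one filtered trait per taxon: plant
flowering onset tracking the 15-years-ago landscape, bird brood number
tracking the 40-years-ago hedgerow amount). `python analysis/01_simulate_study.py`
prints the design:

```
windows: 20, years: 40_years_ago, 15_years_ago, current
  40_years_ago: grassland  24.9% (windows without: 5), hedgerows  6.29 km (windows without: 2)
  15_years_ago: grassland  12.2% (windows without: 5), hedgerows  4.50 km (windows without: 2)
       current: grassland  10.7% (windows without: 5), hedgerows  3.88 km (windows without: 2)
hedgerow_plants: 18 windows surveyed, richness 47-110 (mean 77)
grassland_plants: 15 windows surveyed, richness 39-72 (mean 56)
birds: 20 windows surveyed, richness 12-28 (mean 21)
```

`04_null_models.py` classifies each trait (excerpt):

```
grassland_plants (df = 14):
  flowering_onset      NM2 t=  -11.64 ***  -> convergent
  seed_mass            NM2 t=   -0.47  ns  -> random
birds (df = 19):
  brood_number         NM2 W=   42.00   *  -> convergent
```

The two ground-truth filters are recovered as convergent; the twelve
neutral traits come out random apart from one false positive (hedgerow
flowering duration, the ≈ one expected at α = 0.05 over twelve tests).
`05_landscape_models.py` then fits the gated responses at all three years:

```
selected model years per response (dAICc < 2, normal residuals):
  birds              cwm_brood_number         40_years_ago  (best R2 0.73)
  birds              cwv_brood_number         40_years_ago  (best R2 0.89)
  grassland_plants   cwm_flowering_onset      15_years_ago  (best R2 0.94)
  grassland_plants   richness                 current  (best R2 0.47)
```

AICc selection recovers both planted lags: the bird trait models select
the 40-years-ago landscape and the grassland trait models the 15-years-ago
landscape — the extinction-debt signature the method is designed to
detect. Tables mirroring this output land in `results/`.

The same stages run on user data through the CLI
(`traitscape metrics|indices|nullmodels|all`), which reads plain CSV maps,
GeoJSON hedgerow networks, and CSV survey/trait tables.

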