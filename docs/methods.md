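# Methods

`traitscape` implements a trait-based analysis of how current and past
landscape structure shapes plant and bird assemblages in agricultural
landscapes, together with a synthetic-data generator that emulates the
underlying field design with a known, tunable ground truth. This note
records the models, the defaults and why they are what they are, the
numerical choices, and what the synthetic tests do and do not show.

## 1. Landscape structure

Each sampling unit is a 1 km × 1 km **landscape window**, described by a
raster of seven land-use classes (grassland, hedgerow, crop, orchard,
artificial, woodland, water) plus a polyline layer of hedgerow segments.
Hedgerows are carried as lines because their two metrics — total length and
number of disconnected networks — are line-native; their rasterised cells
also count as an areal class in the whole-landscape metrics (they are one
of the seven land-use types).

Six predictors are computed per window × year:

* **Compositional heterogeneity** — Shannon diversity of land-use areal
  proportions, `H = −Σ p_c ln p_c` (nats). 0 for a single-class window.
* **Configurational heterogeneity** — `−ln(MPA)` where MPA (m²) is window
  area divided by total patch count (connected components within each
  class; 8-connectivity by default, the Fragstats convention, configurable
  to 4). The log tames skewness; the sign reversal makes larger values mean
  more heterogeneous. `MPA × patch count = window area` holds exactly.
* **Grassland amount** — percent of window cells that are grassland.
* **Grassland isolation** — mean nearest edge-to-edge Euclidean distance
  (m) between grassland patches, computed on patch boundary-cell polygons
  (the ENN convention, not centroid distance). Windows with fewer than two
  patches carry NaN, which propagates as a missing value: such windows are
  dropped listwise from any model using the predictor. Amounts, by
  contrast, are 0 for absent habitat.
* **Hedgerow amount** — total segment length (m).
* **Hedgerow isolation** — number of disconnected hedgerow networks:
  segments are graph nodes, joined when they intersect or come within a
  snap tolerance (default 0.5 m — digitised junctions rarely meet exactly);
  components are counted with a sparse union-find.

Predictor collinearity is screened with Spearman correlations across
windows (flag threshold 0.87). Crop percentage is not a predictor: it is
strongly negatively correlated with grassland amount.

## 2. Functional structure

For trait *j* and window *k*, with `P_ik` species *i*'s weight,

    CWM_jk = Σ_i P_ik · trait_ij
    CWV_jk = Σ_i P_ik · trait_ij² − CWM_jk²

Weights come in two schemes: **presence/absence** (equal weights `1/n` over
the *n* species recorded) and **occurrence rate** (a species' share of the
window's pooled occurrence counts). Both are normalised to sum to 1 within
a window, so CWM is a genuine weighted mean and is richness-independent;
an unnormalised presence scheme would make "CWM" grow with richness, which
contradicts its definition as a mean. The one-pass CWV identity can return
a tiny negative number by cancellation; values above `−10⁻¹² · scale²`
(scale = the window's largest |trait value|) are clamped to 0, anything
more negative would indicate a bug and triggers a warning.

Trait tables are completed before use: several values per species are
averaged; a species missing a trait inherits its genus mean; species with
neither are dropped with a warning. The imputed fraction is reported (the
emulated study imputed < 2% of species). Trait redundancy is screened with
Spearman correlations over species (warning threshold 0.7).

## 3. Null models and the effect size

Whether a trait's CWV departs from chance is judged against two
permutation null models, 999 replicates each by default:

* **NM1 (species selection)** asks whether trait values influence which
  species are *present*. Richness is fixed; identities are redrawn from the
  regional pool without replacement, successive draw probabilities
  proportional to regional relative abundance. CWV is computed on equal
  (presence) weights. Weighted sampling without replacement is ambiguous
  between fixed inclusion probabilities and successive draws; successive
  proportional draws are used (`numpy.Generator.choice(replace=False, p=·)`).
* **NM2 (species occurrence rate)** asks whether trait values influence
  which species *dominate*. Richness and identities are fixed; the window's
  occurrence-rate weights are shuffled uniformly among its species. One
  shuffle serves all five traits of a window (each trait reads its own
  column), which is statistically equivalent per trait and much cheaper.

The observed CWV is located in its null distribution by the rank-based
effect size

    ES = ((N(null < obs) + N(null = obs)/2) / (n_null + 1) − 0.5) × 2

with the denominator written generally: it is the printed 1000 at the
default 999 replicates and keeps ES well-scaled for any replicate count.
ES ∈ [−1, 1]; negative means convergence (unusually low variance), positive
divergence. A rank statistic is preferred to a z-score standardisation
because null CWV distributions are typically skewed. Ties are judged at
relative tolerance 10⁻¹²: exact ties are common (e.g. shuffles of equal
weights reproduce the observed CWV exactly) and splitting them in half
keeps the statistic centred. Note the half-step discreteness: with the
observed value at the exact centre of 999 nulls, ES is 0 only when the
tie-split rank reaches 500/1000 (e.g. 499 below + 2 tied); 499 below + 1
tied gives −0.001.

Per trait and null model, the window ES values are tested against zero:
Shapiro–Wilk at α = 0.05 chooses between a one-sample Student's *t*
(df = n − 1) and a one-sample Wilcoxon signed-rank. Verdicts: *convergent*
if significant with central ES < 0, *divergent* if > 0, else *random*.
All-identical ES values are degenerate; the verdict is read from the sign
with p reported as NaN and a warning. α = 0.05 throughout, uncorrected
across traits — with 12 neutrally-assembled traits in a run, roughly one
false positive is expected, and single runs of the demonstration analysis
do show one.

**Gating.** Only occurrence-rate indices are modelled against landscape
structure downstream: CWV of a trait when its NM2 verdict is non-random,
CWM only when convergent (a divergent trait has no single optimum for its
mean to track). Species richness is always modelled.

## 4. Landscape-response models and time lags

Each response is regressed by OLS on one year's predictors at a time —
never a pooled model, because the same predictor at different years is
strongly collinear. Plant groups use four predictors (both heterogeneity
components + their habitat's amount and isolation); birds, surveyed across
the whole window, use all six. Models are full models: per-predictor
two-sided *t* tests are reported with no within-year stepwise selection.

Years are compared by the small-sample-corrected Akaike criterion,

    AICc = AIC + 2k(k + 1) / (n − k − 1)

with *k* counting all coefficients including the intercept. Every year
within ΔAICc < 2 of the minimum **and** with Shapiro–Wilk residual
normality p ≥ 0.05 is *selected*; a low-AICc fit with non-normal residuals
is reported but not selected. A past year selected over the current one is
the signature of a time-lagged (relaxation/extinction-debt) response.
Singular designs raise an error naming a collinear pair; fits require at
least k + 3 complete windows.

## 5. The synthetic-data generator

The generator defines the study conditions; everything downstream is
tested against it.

**Landscape series.** Twenty windows. Each earliest-year map is a Voronoi
mosaic: seed points (8–80 per window, geometrically spaced then shuffled)
control configurational heterogeneity; class-assignment probabilities
(grassland share 0.15–0.60 across grassland-bearing windows, crop half the
remainder, a Dirichlet split over the minor classes) control compositional
heterogeneity — two independently tunable gradients. Hedgerows are drawn
from a 100 m lattice with window-specific keep-probability 0.12–0.50
(≈ 2.6–11 km per window, a realistic *bocage* range). Five windows never
have grassland and two never have hedgerows, matching the emulated survey
design (and hence the across-window test df of 14, 17 and 19).

Later years **derive** from earlier ones — never regenerated — so lagged
signals are well defined: per interval, a fraction of grassland cells
(means 0.40 then 0.15, the big conversion wave first) moves to crop by
converting whole Voronoi patches plus a column-ordered partial patch to
hit the cell budget exactly, and a fraction of hedgerow length (means
0.35 then 0.15) is removed segment-wise. Per-window intensities are Beta
draws around the interval mean (concentration 3) — windows intensify
unevenly, which is also what decorrelates the years enough for lag
recovery to be identifiable. Unless full conversion is configured,
habitat-bearing windows keep a remnant (≥ 2% of cells; ≥ 2 segments) so
the designed habitat-free counts stay exact.

**Species pools.** Sizes 241 / 173 / 84 (hedgerow plants, grassland
plants, birds). Traits are drawn per the pool ranges and moments
(log-normal with moment matching when SD > mean — seed mass, body mass —
else normal; clipped to range; ordinal indices rounded). Regional
abundances are log-normal (σ = 1.5), normalised to 1.

**Communities.** A two-stage occupancy model per window:

* *Incidence*: species *i* is recorded when it occurs in ≥ 1 of the
  window's `M_k` quadrats/points, each with probability
  `min(b·a_i·u_k·f_ik, 0.95)` — regional abundance `a_i` makes common
  species present in more windows; `u_k` is a small landscape-independent
  window effect (log-SD 0.25). The scale `b` is solved by bisection so the
  expected richness matches the emulated study's midpoints (83 / 55 / 21);
  survey effort (12–27 grassland plots × 16 quadrats; 8–20 hedgerow
  sections × 10 quadrats; 4 bird points) is drawn independently of the
  landscape.
* *Dominance*: given presence, the count is `1 + Binomial(M_k − 1, q_ik)`
  with `q_ik` log-normal (σ = 1.5) around a per-taxon local occupancy
  (0.1 for plant quadrats; 0.45 for bird points — a present territorial
  bird is heard at most of the four points).

The decoupling is deliberate and load-bearing: the NM2 across-window test
treats windows as independent evidence, which requires the weight–trait
pairing to be independent across windows under neutrality. If dominance
were driven by regional abundance, every window would share the same
dominants and a chance alignment of abundance with a trait in the pool
would push all twenty ES values the same way — the test becomes massively
anticonservative (≈ 30% type-I in pilot runs). With dominance set by local
conditions, the neutral NM2 rejection rate calibrates at the nominal 5%.
This mirrors the classic observation that local dominance is set by local
conditions while regional frequency governs incidence.

**Ground-truth filters.** A filter is a Gaussian kernel in min–max
normalised trait space, `exp(−s(z_i − opt_k)²)`, with the optimum an
affine map of a named landscape variable at a named lag year (windows
where the variable is undefined sit at mid-range). A divergent variant
sums two kernels near the trait extremes (z = 0.1, 0.9). Filters target
the **dominance** stage by default (presence sustained by propagule
influx — the mass-effect reading); incidence- or both-stage targeting is
available. Targeting matters: NM2 has essentially no power against a
filter that throttles presence and occurrence equally, because the
presence-filtered pool is already trait-truncated and shuffles reproduce
the observed CWV. Strength has an interior optimum for detectability —
too weak moves nothing, too strong boosts so few present species that the
unfiltered majority of the weight mass hides them. The test configurations
use strength 10 (convergent) and 15 (divergent) on flowering onset, chosen
from power pilots; divergence is only detectable on traits whose pool
spans the trait range (it is invisible on seed mass, whose mass sits at
one end).

## 6. Verification scales and what they show

* **Calibration**: 500 pool + community replicates on one fixed landscape
  realisation (the test conditions on the design, as the field study
  does), single trait, 199 nulls: neutral NM2 rejection 0.05 ± 0.02.
* **Power**: 200 replicates: convergent verdict ≥ 80% at strength 10;
  an unfiltered trait in the same runs stays random ≈ 95%; divergent
  verdict in the majority of 100 replicates at strength 15.
* **Lag recovery**: 200 full replicates (landscape regenerated each time,
  20 m cells) with the filter driven by the earliest year's grassland
  amount: AICc selection picks that year more often than either other
  year; with zero conversion the three years' predictors — hence AICc —
  coincide exactly and all three are selected.
* **Oracle equivalence**: CWM/CWV vs a two-pass weighted-moment oracle
  (10⁻⁹); patch counts vs brute-force flood fill; network counts vs
  pairwise union-find; ES vs direct evaluation of its formula; OLS vs the
  normal equations.

Replicate counts, null counts, and cell sizes in the test suite are the
package's chosen verification scales: large enough for the stated
tolerances (e.g. 500 Bernoulli(0.05) replicates give SE ≈ 0.01 against a
±0.02 band), small enough to run routinely.

What passing does **not** show: the generator draws traits independently
(real trait syndromes correlate), assembles species independently given
the filters (no biotic interactions), knows no spatial autocorrelation
between neighbouring windows, no observer error, and its landscape change
is a stationary two-parameter process. Calibration and recovery results
therefore validate the inference machinery, not the ecology of any real
landscape.

## 7. Known limitations

* NM2 power for birds is intrinsically modest: occurrence rates built from
  four point counts take five values, so dominance contrast is coarse —
  as it is in the real design.
* The ES across-window tests remain sensitive to shared structure between
  windows whenever a *filtered* trait correlates with an unfiltered one or
  optima are similar across windows; mild leakage of a strong filter into
  other traits' type-I rates (≈ 0.05 → 0.09 in pilots) is visible at
  strength 15+.
* Grassland isolation uses boundary-cell polygon distances; on very large
  rasters this is the slowest metric (quadratic in patch count).
* The pipeline models each response independently; no correction is made
  for testing several responses per group, matching the emulated
  reporting convention.
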