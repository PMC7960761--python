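# Methods

## The osmoscan and its indices

Osmotic-gradient ektacytometry records the red-cell elongation index (EI)
while extracellular osmolality is swept from 0 to 500 mOsm/kg at a fixed
shear stress of 30 Pa and 37 °C. The informative trace rises through a
small sub-lysis bump, falls to a hypoosmotic valley, climbs to its global
maximum, and descends through the half-maximum level on the hyperosmotic
arm. Seven indices summarise it: `O_min`/`EI_min` (valley; the point
associated with 50% osmotic lysis), `EI_max`/`O_EI_max` (peak),
`O_hyper`/`EI_hyper ≡ EI_max/2` (half-maximum crossing; hydration marker),
and `Area`.

The instrument vendor's exact algorithmic definitions are proprietary.
This package therefore pins its own conventions explicitly; they are
documented choices, not claimed identical to the instrument software:

* **Preprocessing.** Points are sorted by osmolality; duplicate
  osmolalities are replaced by their mean EI (flag `DUPLICATE_OSM`); points
  outside [0, 500] are dropped; EI is smoothed with a centred moving
  average of width `smooth_window` (default 5 samples, must be odd, 1
  disables) that shrinks symmetrically at the ends. Fewer than 20 surviving
  points is the only hard error. A curve carries a `preprocessed` marker so
  preprocessing is exactly idempotent — smoothing is never applied twice.
* **Peak.** `EI_max` is the global maximum of the smoothed EI; `O_EI_max`
  is the mean osmolality of the contiguous run of points within
  `plateau_tol` (default 0.001 EI) of the maximum that contains the argmax.
  The same plateau rule, applied to minima, resolves the valley.
* **Valley.** Global minimum restricted to `[search_lo, O_EI_max]` with
  `search_lo = 100` mOsm/kg by default, which excludes the sub-lysis bump.
  The minimum must be interior to the window; a boundary minimum means the
  curve has no valley there (`NO_VALLEY`).
* **Half-maximum crossing.** The first downward crossing of `EI_max/2`
  beyond the peak, located by linear interpolation between the bracketing
  samples. The first (not last) crossing is used because late-arm noise
  ripples can generate spurious re-crossings. No crossing before the last
  sample flags `HYPER_NOT_REACHED`.
* **Area.** Trapezoidal integral of the smoothed EI over
  `[O_min, O_hyper]`, with the endpoint EI values linearly interpolated.
  These bounds make Area well defined exactly when both anchors exist.
* `EI_max` below 0.05 flags `LOW_SIGNAL` (indices still reported).
  Degenerate shapes never raise: undefined indices are `None` plus a flag.

## Synthetic curve generator

No parametric form for the physical curve is assumed anywhere in the
extraction code. The generator exists to provide curves whose true indices
are known exactly, so extraction accuracy can be measured rather than
asserted. The noiseless trace is a monotone piecewise cubic (PCHIP)
through control knots at the curve start `(start_osm, 0)` (default
50 mOsm/kg — the sweep nominally starts at 0, but below lysis the trace is
uninformative), the bump, the valley, the peak, the half-maximum point
`(O_hyper, EI_max/2)` (exact by construction) and `(500, end_ei)`. PCHIP
gives zero slope at the bump, valley and peak automatically and is monotone
between knots. Symmetric *shoulder knots* are added at valley ± 12 mOsm/kg
(EI + 0.008) and peak ± 15 mOsm/kg (EI − 0.01), clipped to 40% of the
neighbouring segment spans: they pin a definite, locally symmetric
curvature at each extremum so its location is well posed for any symmetric
estimator (a bare zero-slope knot can leave the spline nearly flat on one
side, which makes "the" extremum location ill-conditioned). Ground-truth
Area is the exact spline integral over `[O_min, O_hyper]`. Noise is
additive homoscedastic Gaussian on EI (the simplest testable choice; sd
configurable, default 0 for presets).

Preset phenotypes (WB, WBP, L, M, H) encode the qualitative fraction
profile: `O_hyper` L > M > H, Area smallest for H, `EI_max` M > L > H,
`EI_min` largest for H, `O_EI_max` largest for M, `O_min` equal across
L/M/H, and WBP = WB shifted by +15 mOsm/kg on `O_min` and `O_hyper` only
(the centrifugation swelling artifact). Only these orderings are
constrained by the underlying study, which prints no absolute index
values; the preset levels (WB: `O_min` 140, `EI_min` 0.18, `O_EI_max` 300,
`EI_max` 0.60, `O_hyper` 460) are plausible-range implementation constants,
and every test compares against generator truth, never against them.

## Cohort and fraction simulator

The cohort generator reproduces the composition of a 45-donor healthy
study: 28 women with ages uniform on [18, 61] years and 17 men on
[23, 51] (only ranges are published, hence uniform). Red-cell indices are
normal with the published means ± sd: haemoglobin and haematocrit
gender-specific (F: 136.6 ± 7.67 g/L, 41.4 ± 2.69%; M: 151.5 ± 8.92 g/L,
46.2 ± 3.07%), MCV 89.6 ± 2.58 fL, MCHC 334 ± 11.9 g/L and RDW
13.2 ± 0.51% shared. Hypochromic-RBC percentages are uniform on [0, 4.9]
so every simulated donor passes the < 5% iron-deficiency gate, as all
study donors did.

Whole-blood `O_hyper` follows

```
O_hyper = β0 + β_age · age + β_water · (w − w̄) + σ · ε,   corr(ε, RDW) = ρ
```

with defaults `β_age = 0.3` mOsm/kg/year (the published direction is shown
only graphically; the positive sign is inferred from the upward trend and
the positive RDW association, and is configurable), `β_water = 300`
mOsm/kg per unit water fraction, `σ = 8` mOsm/kg, `ρ = 0.5`, and
`β0 = 448.4` so the mean sits at the WB preset at the cohort mean age.
Water fraction is centred at 0.65 with a negative MCHC coupling
(−0.0009 per g/L), reflecting that MCHC is inversely related to cell
hydration. RDW is drawn jointly with the `O_hyper` residual so its marginal
distribution keeps the calibrated mean and sd. The remaining indices are
preset values plus independent noise (sd 2 mOsm/kg on osmolality indices,
0.008 on EI indices, 3 on Area).

Per-fraction samples add the preset offsets plus smaller independent noise;
the marker panel is log-normal around fraction-specific geometric means
(flow-cytometry fluorescence is positive and right-skewed, and geometric
means are the reported summary), with a log-scale sd of 0.04 and adjacent
log-gaps wide enough that all ten expected orderings also hold per donor in
well over 95% of draws:

* band 4.1a:b ratio rising L < M < H (the deamidation age clock);
* reticulocyte and CD71 positivity maximal in L;
* EMA (band 3 / membrane surface) and forward scatter declining L → H;
* side scatter maximal in H (irregular, echinocytic shapes);
* reduced thiols (mBBr, ThiolTracker) declining L → H;
* oxidant production (DHR) maximal in L; NO (DAF) L > H > M.

The published description of the EMA direction is internally contradictory
(one sentence asserts both the strongest and the lowest staining for the
dense fraction); the generator follows the membrane-surface-loss
interpretation, EMA decreasing from L to H.

## Statistical procedure

Paired comparisons are gated by a Shapiro–Wilk test **on the paired
differences** (the quantity the t-test assumes normal; the gate level is
α = 0.05): p ≥ α selects the paired Student t-test (estimate = mean
difference with 95% CI), otherwise the Wilcoxon signed-rank test
(estimate = median difference). Constant differences are degenerate for
Shapiro–Wilk and fall back to the rank test with a warning; identical
samples return estimate 0, p = 1 by convention. Estimates are oriented as
x − y. No multiple-testing correction is applied by default, matching the
source procedure.

Linear models are OLS of one index on covariates (default age + gender,
gender coded as a two-level indicator, main effects only — no interactions
are modelled), with per-coefficient t-tests and the overall ANOVA F. Rank
deficiency raises a collinearity error naming the columns.

Reference intervals are central percentile intervals (default 2.5th–97.5th)
per stratum, using linear interpolation at rank `h = (n−1)q + 1` (pinned
explicitly so results are bit-reproducible across implementations). Strata
with fewer than `min_n = 20` observations are reported with undefined
bounds and a `LOW_N` flag — at the 45-donor pilot scale every age decade is
below this threshold, which is the honest output: the stratified-reference
proposal needs a larger, multi-centre cohort.

## Morphometry

Each labelled mask component yields area (pixel count × pixel_size²),
moment-equivalent-ellipse axes (4·√eigenvalue of the second central
moments) and sphericity = minor/major axis, chosen over Feret-diameter
ratios for noise robustness. Components under 50 px are dropped;
border-touching cells are flagged and excluded from aggregates because
truncated outlines bias areas and axis ratios. Area histograms use
left-closed bins of width 500 (units follow pixel_size; px² at
pixel_size 1). The synthetic oracle packs non-overlapping rotated ellipses
with sampled areas and axis ratios (rejection placement with an attempt
cap) and returns analytic per-cell truth; measured areas agree within
rasterization error (< 3% at the default cell sizes).

## Determinism

Every random draw flows from one integer seed through named substreams
(`numpy.random.SeedSequence` with a stable per-name spawn key), so any
stage can be re-run in isolation and reproduce its output. The pipeline
manifest records the seed and substream names; two runs with the same seed
produce byte-identical tables.

## Problem sizes and what the tests show

The test-suite simulations use the sizes at which the checked properties
are statistically decisive while keeping the suite quick: 100–300 random
curves for extraction accuracy, 200 noise replicates, 2000 replicates for
the size of the gated test, 200 cohorts of n = 1000 for slope recovery and
CI coverage, 500 replica cohorts for calibration, and 100–200 donors for
fraction and marker orderings.

Passing tests show that the extraction conventions recover known truth on
curves of the modelled shape and that the simulators have the calibrated
moments and orderings. They do not show agreement with any physical
instrument: real osmoscan traces have autocorrelated, heteroscedastic
noise, instrument-specific preprocessing, and curve shapes outside the
monotone-piecewise-cubic family (e.g. pathological double peaks), and the
marker panel units match no particular cytometer. The Percoll handling
artifact is modelled as a pure additive shift; real handling effects may
alter curve shape as well as position.
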