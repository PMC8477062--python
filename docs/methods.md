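# Methods

This note documents the models implemented in `dendrocomp`, the
assumptions they rest on, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions that a maintainer would otherwise have to reverse-engineer.

## Ring widths, BAI, and chronologies

Ring widths are radial increments (mm/yr) measured at breast height;
dating is trusted input (cross-dating quality control is out of scope).
When a tree has two cores they are averaged year-wise into one tree-level
series *before* BAI conversion — basal-area increment is a property of the
tree — but kept separate for the interseries statistics, which describe
cores. BAI uses the annulus formula on the cumulative radius with a
configurable pith offset (`r0_cm`, default 0: plantation cores reach the
pith). Bark is excluded throughout.

Detrending is regional curve standardization: in an even-aged plantation
every ring's cambial age is known exactly (`year − planting_year + 1`), so
the mean width at each cambial age across all cores of a site is a
defensible regional curve. The raw age means are smoothed with a cubic
smoothing spline whose 50%-amplitude frequency cutoff is 10% of the
maximum age (penalty λ = (T/2π)⁴ in the ∫f″² form); the fraction is
configurable. Indices are ratios (width / expected width at age), making
chronologies invariant to rescaling all widths by a constant — the scale
never enters downstream statistics. A ratio index of an identical-core set
is 1 only up to the spline's smoothing bias (≈0.2% in tests), which is the
price of a smooth curve.

Prewhitening fits an AR(p) per core, p ∈ {0..3} chosen by AIC, and keeps
the residuals re-centred to mean 1 (the "residual chronology" convention);
non-stationary fits and constant series fall back to p = 0. Note AIC's
known overfitting: on white noise it still selects p ≥ 1 about a quarter
of the time. The yearly chronology value is the arithmetic mean across
cores — a biweight robust mean is available behind a flag but is unstable
at the 9–12 cores per plot typical of plantation sampling. Rbar is the
mean pairwise Pearson correlation over common periods (≥ 20 yr), and EPS
and SNR follow the Wigley closed forms with n = mean sample depth, so
EPS = SNR/(1+SNR) holds identically.

## Competition and its reconstruction

The Hegyi index sums `(D_j/D_i)/d_ij` over neighbours within 8 m; class
cut-points are low < 1 ≤ medium < 3 ≤ high with half-open intervals
(boundary values 1.0 → medium, 3.0 → high). 30 × 30 m plots cannot host an
8 m buffer, so edge handling defaults to *no correction* with a per-tree
`edge` flag; an optional linear-expansion correction divides an edge
tree's CI by the fraction of its search disc inside the plot (computed on
a deterministic 64×64 grid). The correction can only increase CI, never
produce a negative one.

The annual reconstruction follows the growth-rate method: cored trees give
`GR_k = RI_k/ΣRI`; the plot growth rate is the year-wise mean over cored
trees on their common span, renormalized to sum to 1. Non-cored diameters
are back-cast as `D_k = D_obs · Σ_{j≤k} GR_j` (the rate path: the method's
first assumption maps over-bark diameter growth *rates* to under-bark
radial rates, not magnitudes), cored diameters by subtracting their own
future increments `D_k = D_obs − 2·Σ_{j>k} w_j/10`. Both paths close
exactly (bitwise) on the observed DBH in the final year. The second
assumption — a single even-aged cohort with no mortality — is enforced:
cores implying in-growth are rejected unless explicitly allowed.
Reconstructed DBHs below 1 cm are years in which the stem had not reached
breast height; any participant below that floor makes the year's CI
undefined rather than meaningless. Cored neighbours enter the competitor
set by default (their back-cast histories are the best available); a flag
restricts competitors to non-cored trees.

## Climate derivatives

VPD is `e_s(T)·(1 − RH/100)` with the Magnus saturation curve. PET is
Thornthwaite's temperature-and-latitude method — chosen because the
station variables the pipeline requires (T, P, RH) guarantee its inputs;
which PET formulation "the" SPEI should use is genuinely open, and results
shift slightly between Thornthwaite and Penman variants. The heat index
uses the record's own monthly climatology; months at or below 0 °C get
PET = 0; the hot-month polynomial replaces the power law above 26.5 °C;
latitudes beyond ±66° are outside the day-length formula's domain.

SPEI aggregates the climatic balance D = P − PET over a backward k-month
window and standardizes each calendar month's sample separately over the
full record (the calibration period, matching common usage). The
distribution is fitted by unbiased probability-weighted moments in the
generalized-logistic parametrization: for positively skewed samples this
*is* the 3-parameter log-logistic (shape k = −1/β); it extends continuously
to negative skew, which matters here because imposing severe droughts
drags the left tail of the growing-season balance sample (observed skew
≈ −0.9) to where the pure log-logistic branch has no solution. Fitted
probabilities go through `scipy.stats.norm.ppf` (no rational
approximation) and are clipped to [1e-6, 1−1e-6], capping |SPEI| ≈ 4.75 so
imposed extremes stay finite. Start-up months (first k−1) and degenerate
samples are NaN, never zero-filled.

The growing-season SPEI is one value per year: the April–October balance
sum, fitted to the one-per-year sample (n = number of years) — each year
contributes exactly one value, which is the quantity the drought-year
criterion thresholds.

Station screening: Mann–Kendall with tie-corrected variance and
continuity-corrected z (slightly conservative — measured null rejection
0.042 at α = 0.05, n = 40), and a double-mass screen that fits a
two-segment line to cumulative candidate vs cumulative reference and flags
slope-ratio deviations beyond 10% (configurable).

## Climate–growth screen

The correlation window runs from the previous October to the current
September — 12 monthly cells per variable (precipitation, mean
temperature, RH, VPD, 1-month SPEI; max/min temperature when present).
Because late-season effects can extend into the current October, the
window end is configurable (`C_Sep`/`C_Oct`). Pearson r with the exact
t-distribution p per cell; **no multiple-testing correction by default** —
the screen reproduces conventional per-cell starring, so ~5% of cells will
be starred under a pure null; it is a ranking device (top-|r| significant
cells feed the attribution model), not family-wise inference. Bonferroni
is available behind a flag.

## Attribution

Five-year non-overlapping block means (trailing block kept if ≥ 3 yr)
align the slowly varying competition and site covariates with climate.
The growth model is OLS of block-mean log BAI on the screened climate
factors, the reconstructed plot-mean CI, and the site index — "site index"
is dominant height at a base age of 40 yr, an *input* covariate (the
height-age model behind it is site-specific and not reimplemented;
synthetic fixtures derive it from a Richards curve). Cambial age is
deliberately excluded: it is an inherent factor whose log–log relation
with BAI would absorb variance belonging to the three causes under study.
No random effects: the design specifies exactly three fixed inputs (plot
random intercepts exist behind a flag for sensitivity checks).

LMG importance averages a group's incremental R² over all group-entry
orderings, computed exactly via subset-R² caching up to 10 groups (seeded
ordering sampling beyond, flagged approximate). Shares are non-negative,
sum exactly to R², and equal marginal-r² proportions for orthogonal
groups. Whether shares should be displayed as percent of explained or of
total variance is ambiguous in common usage; both are reported,
percent-of-R² being the default display.

## Drought events and resilience

A severe drought year has growing-season SPEI < −1. Sub-threshold years
separated by ≤ 3 years belong to the same event (legacy effects last 1–2
years; a multi-year dry spell must not be double-counted); events must be
separated by *more* than 3 years. An event's member years are its drought
years only — BAI during the event (`BAI_D`) averages those years (not the
worst year; the "mean BAI during a drought event" reading).

Indices are computed per tree on **raw** BAI; the 3-year moving average
(centred, 2-yr means at the ends) is a display and event-inspection aid,
with a `smoothed` flag to compute indices on the smoothed series instead —
the two conventions coexist in the literature. Pre/post windows are the 3
years immediately before/after the event; if another event's drought years
intrude, the window slides outward by up to 2 years to find 3 clean years,
else the index is undefined and reported as such (strict exclusion applies
to event years only — windows that merely touch between close events are
accepted, as they must be when real events fall 6 years apart).

Group contrasts report mean ± sd ± n per (site, event, class) with
pairwise **Welch t-tests, a labelled stand-in** for the classical post-hoc
LSD ANOVA machinery (out of scope). The density-dependence statistic is
the Pearson correlation of per-tree modeled CI (reconstructed, averaged
over the event years) with each index, pooled across classes per event.

## The synthetic generator

The generator emulates: rectangular even-aged plots (jittered-lattice
positions, so stems never coincide and density is `⌊area × density⌋`),
three density classes per site sharing one climate; a semi-arid monthly
climate — sinusoidal temperature (optional trend), gamma-distributed
precipitation peaking in July–August totalling ~440 mm/yr, noisy sinusoidal
RH; and imposed droughts that scale April–October precipitation by
exp(−severity), calibrated so a severity ≈ 2 event lands below the
SPEI = −1 threshold after the full SPEI computation.

Growth is multiplicative on the log scale:
`w = A(age)·exp(β·z − γ·CI − λ·CI·L + ε)`, with a negative-exponential age
trend A (3.5 → 0.8 mm, τ = 12 yr), z the z-score of the record's own
April–October balance, CI the *true* Hegyi index recomputed yearly from
simulated diameters (DBH accumulates 2×width from a 0.5 cm seedling
caliper, so final DBH closes exactly on the ring sums), and L an indicator
of the 2 years following any realized severe-drought year (z < −1.3). The
λ·CI·L term is the drought-legacy × competition interaction: the drought
year itself is depressed only through the climate term, so *resistance*
stays density-independent while recovery and (relative) resilience decline
with crowding — the qualitative structure the resilience stage is designed
to detect. The log-linear form is chosen to make parameter recovery by the
log-BAI attribution model well-posed. Defaults (β = 0.30, γ = 0.06,
λ = 0.08, σ = 0.10) are fixed study conditions giving realistic magnitudes
(CI 0.5–5 across 250–900 trees/ha; drought years halve ring width;
crowded trees lose ~20–25% of post-drought growth).

Per-tree, per-substage `SeedSequence` streams make output bit-reproducible
and insensitive to adding trees. Heights are allometric in DBH (saturating
at ~23 m) — there is no height growth model; no mortality, regeneration,
or thinning dynamics; climate has no spatial structure within a site; and
ring-width noise is i.i.d., with none of the autocorrelated measurement
error or missing/locally absent rings of real cores. Passing tests
therefore demonstrate correctness of the *methods* under the stated
generating process, not that real stands satisfy its assumptions.

## Problem sizes and numerical choices

The default simulated site (three 30 × 30 m plots at 250/550/900 trees/ha,
45 years, ~150 trees) keeps a full pipeline run under a second and the
recovery experiments (50 replicate sites) around a minute; the SPEI
calibration checks use a 500-year drought-free climate. Determinism:
outputs are byte-identical across re-runs — LMG subset iteration is
ordered explicitly (frozenset iteration depends on string hashing), CSVs
are written with a fixed float format, and the manifest carries a config
hash instead of timestamps. Degenerate inputs are errors, not silent
repairs: coincident stems within the search radius, zero total increment,
zero-variance references, rank-deficient designs (reported with the
aliased columns), non-contiguous ring years.

## Known limitations

* The Tucson writer/reader uses the conventional 999 terminator in
  0.01 mm units, so a genuine final ring of exactly 9.99 mm cannot be
  represented.
* The double-mass screen locates a single break; multiple inhomogeneities
  are reported only as the best two-segment fit.
* Edge correction is a first-order area expansion; it ignores the spatial
  pattern of off-plot neighbours.
* The attribution chain screens climate factors on the pooled
  first-differenced growth signal; with very short records (< 15 common
  years) the screen refuses to run rather than report unstable
  correlations.
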