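# Methods

## The modeling problem

A prospective matched repeated-sampling design provides, for every
future case, a tightly matched control and two samples per subject: a
baseline and a repeated sample collected closer to the case's
diagnosis. The scientific question is *when* a disease-related
multivariate pattern becomes detectable: how many years before
diagnosis (ttd, anchored to the case's repeated sample), and under how
long a baseline-to-repeated interval (tbs) the baseline still serves as
a valid within-subject reference. Both coordinates are continuous years.

The paired transforms

    X_progress        = X_repeated − X_baseline            (per subject)
    d                 = X_progress(case) − X_progress(control)   (per pair)

cancel, in order, the subject's individual baseline and the shared
effects of elapsed time and storage. For single-time-point cohorts the
analogous transform is `d = X_case − X_control`, with no tbs coordinate.

## OPLS effect projections (EP)

OPLS decomposes a predictor matrix into one component correlated with a
response and orthogonal components uncorrelated with it. The EP variant
treats the paired-difference matrix `D` as predictors for a constant
response y = 1: after dividing each column by its sample standard
deviation (n − 1 denominator, no centering — the zero point of a
difference is meaningful), the predictive weight is w ∝ Zᵀ1, i.e. the
vector of scaled column means. The sign of w is canonicalized (largest
weight positive) so that negating the data negates scores. With one
variable the score t-test `mean(t)/(sd(t)/√n)` is *exactly* the paired
two-tailed t-test; this equivalence, checked to 1e−10, is the module's
primary oracle. Orthogonal components, when requested, are extracted
by deflating the loading part orthogonal to w before the final
predictive fit. The default for subset models is a single component —
twenty observations cannot support more without overfitting.

Two per-variable statistics describe each model:

* **w criterion** — paired t on the raw difference column,
  t = mean/(sd/√n), two-tailed with n − 1 df;
* **p criterion** — uncentered cosine similarity cs between the
  sd-scaled column and the model-estimated response ŷ = b·t, tested via
  t = cs·√(n − 1)/√(1 − cs²) with n − 2 df. The uncentered cosine (not
  Pearson r) matches the uncentered EP geometry.

A variable is *multivariate significant* when the model is significant
(CV-ANOVA p < 0.05) **and** both criteria give p < 0.05. Univariate
summaries additionally apply Benjamini–Hochberg FDR at 0.2.

## Cross-validation and CV-ANOVA

Model significance uses k-fold cross-validation (default k = 7,
balanced folds from a seeded permutation; the seed is recorded in every
output). Inside each fold, only variables passing both per-variable
criteria (p < 0.05) *on the training part* are kept, the model is
refitted on those, and the held-out responses predicted. If any round
selects no variable, the model is declared non-computable — a sentinel,
not an exception — mirroring how such models are reported as absent
rather than non-significant. Q² = 1 − PRESS/SS(y) with SS(y) = Σy² = n
for the uncentered EP response (Σ(y − ȳ)² for centered DA).

CV-ANOVA compares the cross-validated residuals against the total
response variation:

    F = ((SS_tot − PRESS)/df_reg) / (PRESS/df_res),
    df_reg = 2·A,   df_res = df_tot − df_reg,
    df_tot = n (EP, uncentered)  or  n − 1 (DA, centered),

where A counts all model components and each component consumes two
degrees of freedom (score direction + score-response regression). The
p-value is the upper tail of F(df_reg, df_res); PRESS exceeding SS_tot
gives p = 1, a zero-PRESS perfect fit gives p = 0 with a flag. Under
null data the test is mildly conservative (measured type-I error ≈ 0.03
at α = 0.05 for n = 64, p = 142): cross-validated PRESS typically
exceeds SS_tot under the null, and the F reference distribution is
approximate. The test controls false positives; it does not spend the
full nominal level.

## The scan

A lattice with 0.25-year steps (configurable) covers the observed
(ttd, tbs) bounding box, aligned to step multiples. At each lattice
point, distances `√((w_t·Δttd)² + Δtbs²)` are computed for the seven
ttd-weights {1/8, 1/4, 1/2, 1, 2, 4, 8} — geometric doubling is the
natural 7-element sequence between the stated endpoints, and is
configurable — and the k = 20 nearest pairs form a subset (distance
ties broken by pair id for reproducibility). Subsets with identical
membership are modeled once; the first proposing anchor/weight is
recorded. Every subset gets the full EP + CV treatment; non-computable
models are kept as non-significant sentinels.

A subset's *position* is the unweighted mean of its members'
coordinates, and its spatial extent is a 95% Hotelling T² ellipse:
Mahalanobis bound 2(n−1)/(n−2)·F₀.₉₅(2, n−2) around the member cloud
(→ χ²₂(0.95) as n grows; collinear clouds degrade to a zero-minor-axis
sentinel that covers nothing). The SMART-observation raster counts, per
cell center, the covering ellipses of significant subsets; per-variable
rasters count subsets where the variable passes a chosen criterion
(t-test / FDR / multivariate), signed by the direction of change.

The region of interest is *declared by the analyst* after inspecting
the outputs (two numbers: ttd_max, tbs_max); no automatic rectangle
estimator is provided, deliberately. The ROI model is a one-component
OPLS-EP on a chosen variable panel restricted to pairs inside the
rectangle.

## Loading clustering

Significant-model weight vectors are clustered with 1 − cosine distance
and average linkage. Cluster count is decided against a simulated 95%
confidence limit: 1000 same-shaped sets of independent standard-normal
loading vectors are clustered, their merge heights pooled, and the
observed dendrogram cut at the lower 5th percentile of those heights.
Random directions in high dimension are nearly orthogonal (distances
≈ 1), so only merges markedly tighter than chance fuse models into one
cluster; random loadings dissolve into singletons, while strongly
overlapping subset models collapse into one dominant cluster. The null
is pluggable (`cluster_models(..., n_null, level, seed)`).

## Null simulation and probability maps

To guard against overfitting-by-scanning, the entire scan is
recomputed under the global null: the difference matrix is replaced by
iid standard-normal draws of the same shape while the coordinates —
hence subset membership and ellipses — stay fixed. Each replicate
yields a density raster; the default replicate count is 10,000 (tests
and the acceptance script use far fewer, with correspondingly coarser
attainable probability floors). Replicate streams are seeded
`(seed, replicate)` so results are independent of execution order and
parallelism; long runs checkpoint and resume. The observed density is
converted per cell with the add-one estimator
p̂ = (1 + #{null ≥ observed})/(1 + R), never exactly zero, and
discretized to the six printed levels ">0.20" … "<0.001" (the floor
"<0.001" requires R ≥ 999).

## Latent biomarker and validation

The latent biomarker is the significant-variable panel plus the
one-component ROI OPLS-EP projection trained on the discovery
differences. Validation pairs (single time point, case − control)
restricted to the panel are scored through the frozen model (training
scaling applied; no centering, so an identical case/control pair scores
exactly zero). Evaluation:

* dependent t-test of the scores for pairs with ttd < window (default
  8 years) — a one-sample t against zero, since scores are already
  paired differences;
* ROC treating ttd < window as the positive condition; midrank AUC
  equals Mann–Whitney U/(n₁n₂) exactly. Significance defaults to the
  two-sample rank-sum test (the two compared groups are independent and
  of unequal size); a signed-rank alternative on the positive-condition
  scores is available behind `rank_test="wilcoxon"`.

## Synthetic data generator

The generator emulates the discovery design: 64 pairs × 142 variables,
baseline + repeated samples, per-pair (ttd, tbs) uniform over
0.5–16 × 0.5–12 years, and a 15-variable panel carrying a case-specific
increase of 1.5 noise-sd in the *repeated case sample only*, confined
to ttd < 8 ∧ tbs < 7 with a 1-year linear taper at the boundary
(margin 0 gives a hard rectangle). Values are baseline level (10) +
subject random effect (sd 1, shared between a subject's two samples) +
measurement noise (sd 1). The subject effect cancels in the progression
transform — the generator thereby reproduces the design's reason for
existing. A validation variant emits one sample per subject with the
effect gated on ttd only. All draws flow from one integer seed;
identical configs give byte-identical tables, and the planted panel can
be pinned explicitly so independent validation draws share the
discovery mechanism.

What the generator does **not** emulate: batch/run-order drift,
heteroscedastic or correlated variables, non-Gaussian marginals,
missingness, and matching imperfections. Passing tests therefore
demonstrate correctness of the machinery and calibration under clean
conditions, not robustness to instrument artifacts.

## Problem sizes and numerical choices

The test suite and acceptance script run reduced designs chosen as the
smallest sizes at which each property is identifiable: scans for
replicate studies use a 1-year lattice with a 0.5-year raster
(single-study examples use the full 0.25-year lattice), null banks use
59–99 replicates (probability floor ~1/60), and Monte-Carlo
calibrations use 400–2000 simulations. Degenerate inputs are handled
explicitly: zero-variance columns are rejected at scaling (or dropped
per training fold inside CV), |cs| = 1 maps to an infinite-t sentinel
with p = 0, zero-spread score vectors give NaN t-statistics, and
collinear ellipse inputs give degenerate sentinels. All tolerances in
tests are stated against exact oracles (1e−10 for algebraic identities)
or binomial/Monte-Carlo error bands for calibration checks.

## Known limitations

* The Hotelling observation ellipses of 20-member subsets are broad
  (semi-axes of several years), so observation-plot density smears
  roughly two years beyond a true effect boundary; the modal density
  cell can land just outside a planted rectangle. Region declaration
  should weigh the probability map, not the raw density argmax.
* CV-ANOVA is conservative under the null (see above); borderline
  models are under-called rather than over-called.
* The cluster-count confidence limit assumes isotropic random loadings
  as the null; correlated-variable nulls would raise the cut height.
* With per-fold variable selection, Q² of a selected-variable model is
  optimized; it should be compared against the null simulation, not
  interpreted as an unbiased effect size.
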