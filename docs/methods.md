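# Methods

`agetrends` models cross-sectional bulk RNA-seq of a lifespan cohort (its
defaults emulate ~88 rhesus-macaque hippocampus samples spanning 3–35 years)
and asks four questions: which genes change with age and how (linearly or
with a midlife turning point), when nonlinear trajectories turn, whether
expression becomes noisier in older adults, and how much of the bulk signal
is cell-composition drift.

## Preprocessing

Counts are converted to log2 counts-per-million with a prior offset:
`log2((count + c) / (lib + 2c) * 1e6)` with `c = 0.5` by default (the offset
used by voom-style pipelines; the value is configurable because the original
analysis names the transform but not the offset). Library size is the raw
column sum of the matrix handed in; when a filtered submatrix must be
normalized consistently, the unfiltered sums can be passed explicitly.
Genes are kept when logCPM exceeds 4.0 (strict inequality; boundary behavior
is configurable) in at least 15 samples. Nuisance covariates (sex,
batch, …) are removed by per-gene OLS residualization; categorical
covariates expand to indicators and a rank check rejects collinear designs
listing the offending columns. No precision weighting is applied: the
trajectory stage has no weighting mechanism, so downstream stages consume
unweighted logCPM or residuals.

A simple marker-score screen (`flag_outlier_samples`) flags samples whose
mean logCPM over a user-supplied marker set sits more than 3 z-units from
the cohort — a lightweight stand-in for contamination screening; the marker
list is the user's responsibility. PCA of sample profiles (genes centered)
plus per-component OLS on age reproduces the standard PC–age association
check (beta, normal-theory 95% CI, two-sided p).

## Per-gene ARIMA trajectories

Samples are placed on an **equally spaced index in age order** (rank space),
with age ties broken by sample id. ARMA likelihoods assume equal spacing and
a cross-sectional cohort has none; rank space is the convention adopted by
the trajectory-modeling approach this stage follows. Calendar age re-enters
only for LOESS smoothing and inflection estimation.

Every order in the grid p,q ∈ {0,1,2} × d ∈ {0,1} (18 models; n ≈ 88
supports no more) is fit by **exact Gaussian maximum likelihood**: the
ARMA(p,q) part is cast in Harvey state-space form, the stationary initial
covariance solves the Lyapunov equation, and the innovation variance is
concentrated out. Remaining parameters — a mean (d = 0 models only; the
constant is dropped after differencing) and partial-autocorrelation-
transformed AR/MA coefficients — are optimized by a deterministic
Nelder-Mead (per-model iteration cap 60·dim, simplex tolerance 3e-4 on the
coordinates, 1e-8 on the objective). The PACF transform keeps AR iterates in
the stationarity triangle and, with a sign flip, MA iterates in the
invertibility region. Slowly trending genes put the optimum in a
persistent-AR basin near the boundary that Nelder-Mead rarely reaches from
the origin, so a second start (leading AR partial correlation 0.9, MA −0.5)
is tried whenever its objective is competitive. On random test series the
optimizer matches or exceeds statsmodels' log-likelihood to within 0.2 nats
on interior optima; true boundary optima (e.g. an over-differenced model
whose MA roots cancel the differencing) are approached but not attained,
which only penalizes models that lose the AIC race anyway. The whole grid
costs ~20–25 ms per gene, which is what makes the simulation-based tests
and reruns feasible on one CPU.

Model selection is minimum AIC (= −2ℓ + 2k, k counting mean, AR, MA and the
innovation variance) with ties broken toward smaller p+d+q, then smaller d.
Orders whose fit fails are dropped with a warning; a gene fails only if all
orders fail. AIC values for d = 1 models are computed on the differenced
series (n−1 points); strictly, likelihoods across different d are not on the
same sample — the convention of differencing-based ARIMA selection is
followed and documented here.

**Fitted trajectories are phase-neutral**: the average of forward and
backward one-step Kalman predictions. A purely forward predictor trails the
underlying trend by its mean lag (~1 sample), which measurably biased
inflection ages rightward (~+1.3 years in pilot simulations); stationary
Gaussian ARMA is time-reversible, so averaging the two directions cancels
the lag.

## Trend significance and FDR

The default test (`lrt`) refers 2(ℓ_best − ℓ_null) to chi-square with
df = max(k_best − k_null, 1), against the constant-mean Gaussian null
(ARIMA(0,0,0) + constant, closed form). When the null itself wins the AIC
race, p = 1 by convention. The df floor covers selected orders with fewer
parameters than the null (e.g. (0,1,0)).

**This p-value is anti-conservative.** The alternative was itself chosen by
AIC, so under pure noise each of the 17 non-null orders is only selected
when its LRT statistic already exceeds 2·df; simulation puts the null
rejection rate at α = 0.05 near 0.25 for the default grid. The pipeline
never interprets raw p-values: genes are called through Benjamini–Hochberg
at q < 0.05, and on all-null cohorts the realized fraction of called genes
stays far below 5% (the BH threshold sits deep in the tail, where the
selection inflation is a bounded multiplicative factor); this is verified by
a 10-seed acceptance test. A `permutation` option (grid search repeated on
age-shuffled series, p = (1 + #{AIC advantage ≥ observed})/(1 + n_perm),
seeded) provides calibrated inference at ~n_perm× the cost and is the robust
choice when raw per-gene p-values matter.

## Clustering, LOESS and inflection ages

Fitted trajectories of the q < 0.05 genes are z-scored per gene and
clustered with Ward linkage on Euclidean distance (the original work names
neither metric nor linkage; Ward on z-scored curves is the common choice for
shape clustering), cut at k = 4 by default — the observed four-archetype
structure; k is configurable and no automatic selection is attempted.
Each cluster is summarized by the pointwise mean and ±1 sd of member
trajectories plus a LOESS curve of the mean against calendar age, predicted
on a 0.1-year grid. The LOESS is a hand-written local quadratic with
tricube weights and span 0.75 (no installed package offers local-quadratic
LOESS with prediction on a new grid); it is exact on polynomials up to
degree 2, which the tests assert.

The **inflection age** is the age of the dominant extremum of the LOESS
curve: both argmin and argmax are located and the one deviating more (in
expression units) from the straight chord joining the curve's endpoints is
reported, with ties toward the younger age. An extremum is *interior* when
it lies ≥ 1 year (margin, configurable) from both ends; flat curves (range
< 1e-10) report a non-interior minimum at the youngest age. Classification:
interior minimum → U-shaped, interior maximum → inverted-U, otherwise the
endpoint difference signs a linear label.

Runs are compared by the overlap fraction |A∩B|/|A| and Jaccard of their DEG
sets, and by the Pearson correlation of per-gene endpoint slopes
((last − first fitted value)/age span) over shared genes — a declared
scalar stand-in for the original coefficient-matrix comparison, whose exact
construction is not public.

## Variance dysregulation

Adults are split into 10–20 years (inclusive) and > 20 years; younger
samples are excluded. Genes whose group logCPM means differ by more than
0.5 (inclusive boundary) are removed so variance is compared at matched
expression. Sex is residualized by one global per-gene OLS across the
included samples; group variances use n_g − 1; F = var_old/var_young with df
(n_old − 1, n_young − 1) and two-sided p = 2·min(tail, 1−tail) capped at 1;
BH across tested genes. Swapping groups maps F → 1/F and leaves p unchanged.

The global test is a paired t across genes on log variances (natural log by
default, configurable). When group sizes are supplied, each log variance is
centered by its sampling bias E[ln(s²/σ²)] = ψ(k/2) − ln(k/2), k = n_g − 1:
without this, unequal group sizes shift E[ln s²] systematically and the
"null" paired difference is nonzero, which simulation shows as a badly
non-uniform p across cohorts. With the correction the null p is uniform
(KS p ≈ 0.9 over 100 simulated cohorts). Reported: t, df = #genes − 1, p,
raw-scale group mean variances, and the mean paired log difference
(young − old; inflated old-age variance gives negative t).

Power caveat: a 1.5× log-sd inflation (variance ratio 2.25) at n = 35 vs 29
has two-sided F power ≈ 0.6 at raw α = 0.05 but only a few percent at the
BH-adjusted threshold, so per-gene detection of modest inflation is sparse
by nature — the global paired t and the old-greater/young-greater asymmetry
are the sensitive readouts, exactly as in the motivating study.

## Deconvolution

The signature is the per-cell-type arithmetic mean expression on the linear
CPM scale over genes shared by all profiles (columns sorted; a condition
number above 1e8 triggers a non-identifiability warning). Proportions are
estimated per sample by **nonnegative least squares** of bulk linear CPM on
the signature columns, renormalized to the simplex, with the residual norm
recorded; outputs carry the label `nnls-stand-in` — this is a deterministic,
dependency-light replacement for support-vector deconvolution, not a
numerical replica of it. Deconvolution operates on the linear scale
(mixing is linear) and applies no quantile normalization. Proportions are
regressed on age per cell type (OLS, 95% CI); because rows sum to 1, the
fitted slopes sum to 0 exactly.

The cell-corrected rerun residualizes expression on intercept + sex +
(k − 1) proportion columns, dropping the largest-mean cell type to break the
sum-to-one collinearity (the dropped column is logged), then reruns the
trajectory stage unchanged. Note a structural fact the tests encode: when
composition itself drifts deterministically with age, proportion columns are
near-affine in age and correction removes genuine age trends (noise-free
planted proportions are exactly collinear and are rejected by the rank
check); correction is benign only insofar as composition varies
independently of age.

## Synthetic cohorts

The generator plants known ground truth so every stage is testable offline.
Defaults mirror the study conditions: 88 samples, ages uniform on 3–35
years at 0.1-year resolution (an explicit age list can be injected to match
a real histogram), 55:33 female:male, 4 round-robin batches, 28% of genes
carrying an age trend split 37.9/43.9/12.3/5.9% among linear-up,
linear-down, U-shaped and inverted-U archetypes (the observed cluster
shares), interior extrema at 10 years, and 1.5× log-sd variance inflation
past age 20 in 10% of genes. Effect sizes default to 0.03–0.06 logCPM/yr
(linear) and 0.002–0.005 logCPM/yr² (quadratic) on a log-scale noise sd of
0.5 — trajectories spanning 1–2.5 log2 units over the lifespan, strong but
commensurate with a cohort where ~28% of genes are detectable. The
desk-scale default is 2,000 genes (the study retained 9,563); gene count is
problem size, not a study condition, and every simulation-based test states
the size it ran at.

A gene's log2 expression is Gaussian around its archetype trajectory
(`dispersion` = log2 sd; `old_var_inflation` multiplies it past the hard
age-20 switch, mirroring the two-group analysis; smooth inflation is out of
scope). The latent logCPM is converted to an expected count under the
sample's library size (uniform 0.7–1.3× around 1e6) and counts are drawn
gamma-Poisson with count-level dispersion 0.01 — small enough that the
log-scale Gaussian dominates the variance budget the variance tests see,
so the planted old/young log-variance ratio converges to
`old_var_inflation²` (tested at n = 2000 samples, ±15%). Optional:
per-gene-per-batch log2 offsets (`batch_sd`) for exercising batch
residualization, and a marker-gene spike for the outlier screen.

Mixtures: six cell types with oligodendrocytes at +0.00099 proportions/yr
and glutamatergic neurons at −0.0017/yr (the two significant drifts in the
study), the remainder spread so slopes sum to zero; proportions are
baseline + slope·(age − midpoint), clipped and renormalized; bulk counts are
gamma-Poisson around proportions × signature. Each type carries a marker
block so the default signature is well conditioned. By default the true
proportions are an exact function of age (which keeps the documented
arithmetic contracts exact but makes a corrected design collinear with age);
`proportion_noise_sd` adds per-sample compositional scatter — ~0.02 is a
realistic inter-individual level and is what the reproduction script uses
for the cell-corrected rerun.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: read-level artifacts (adapters, mapping),
mean–variance coupling beyond the NB draw, correlated gene modules
(co-expression), non-uniform real age histograms, dropout, or the
choroid-plexus contamination transcriptome (only the marker-spike toy).
Archetype recovery rates on real data will be lower than on these clean
planted shapes.

## Determinism and numerics

Every stochastic step takes an explicit seed (simulation, permutation test);
fits, clustering and NNLS are deterministic given inputs, so a full pipeline
run writes byte-identical outputs for identical (config, seed) — enforced by
a manifest of SHA-256 content hashes. Degenerate inputs have defined
behavior: zero library size, constant age, empty age groups, zero-variance
genes (dropped with warning from the global t), rank-deficient designs
(error listing columns), flat LOESS curves (non-interior minimum), all-fail
ARIMA genes (excluded, logged).
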