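# agetrends

Lifespan transcriptomic trajectory analysis for cross-sectional bulk
RNA-seq: which genes change with age, whether they change linearly or turn
at midlife, when the nonlinear trajectories turn, whether expression becomes
noisier in older adults, and how much of the bulk signal is cell-composition
drift. The defaults emulate a hippocampal aging cohort of ~88 primates
spanning 3–35 years of age.

It is written for researchers analyzing gene × sample count matrices with a
continuous age covariate who want to go beyond young-vs-old contrasts and
model the whole lifespan, and it ships a synthetic-cohort generator with
known ground truth so every stage can be validated without external data.

## The method

1. **Normalize and filter.** logCPM = log2((count + c)/(lib + 2c) · 10⁶),
   c = 0.5; keep genes with logCPM > 4 in ≥ 15 samples; residualize sex and
   batch per gene by OLS; PCA with per-component age association
   (β, 95% CI, p).
2. **Per-gene ARIMA trajectories.** Samples are ordered by age on an
   equally spaced index; every ARIMA(p, d, q) with p, q ∈ {0,1,2},
   d ∈ {0,1} is fit by exact Gaussian maximum likelihood (in-package
   Kalman-filter engine, ~20 ms per gene for the whole grid); the
   minimum-AIC model is kept. Its trajectory is tested against the
   constant-mean null — χ² likelihood-ratio by default, a seeded permutation
   test (age shuffles, the whole grid refit) as the calibrated option — and
   genes are called at Benjamini–Hochberg q < 0.05.
3. **Cluster and date the trajectories.** Fitted trajectories of the
   significant genes are z-scored and Ward-clustered (k = 4 by default);
   each cluster's mean curve is LOESS-smoothed (local quadratic, span 0.75)
   on a 0.1-year age grid and the **inflection age** is the interior
   extremum deviating most from the endpoint chord — classifying clusters as
   linear up/down or U / inverted-U.
4. **Variance dysregulation.** Adults split at 10–20 vs > 20 years;
   mean-matched genes (|Δmean| ≤ 0.5 logCPM) get two-sided F-tests on
   sex-residualized variances with BH control, plus a global paired t-test
   across genes on (bias-corrected) log variances.
5. **Deconvolution.** Cell-type proportions by nonnegative least squares of
   bulk linear CPM on a signature matrix (a deterministic stand-in for
   support-vector deconvolution, labeled as such), renormalized to the
   simplex; per-cell-type OLS of proportion on age; and a cell-corrected
   trajectory rerun with expression residualized on sex + proportions.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import agetrends as at

# 1. simulate a lifespan cohort: 88 animals, ages 3-35, 28% of genes with age trends
cohort = at.simulate_cohort(at.CohortConfig(n_samples=88, seed=1))
truths = at.default_gene_truths(n_genes=2000, seed=1)
counts, truth = at.simulate_counts(cohort, truths, seed=2)

# 2. normalize, filter, remove sex/batch effects
logcpm = at.compute_logcpm(counts)
kept = at.filter_genes(logcpm, threshold=4.0, min_samples=15)
expr = at.residualize(logcpm[kept], cohort, ["sex", "batch"])

# 3. per-gene ARIMA trajectories, AIC selection, FDR-controlled trend calls
results, fitted, ordered = at.fit_trajectories(expr, cohort)
degs = at.call_degs(results["p"], fdr=0.05)
print(f"{degs.is_deg.sum()} of {len(degs)} genes ({100*degs.is_deg.mean():.1f}%) change with age")

# 4. cluster the significant trajectories and date the nonlinear turn
labels, _ = at.cluster_trajectories(fitted.loc[degs.index[degs.is_deg]], k=4)
ages = ordered["age"].to_numpy(float)
for c in sorted(labels.unique()):
    summ = at.summarize_cluster(fitted.loc[labels.index[labels == c]], ages)
    infl = at.estimate_inflection(summ["age_grid"], summ["loess"])
    kind = at.classify_trajectory(summ["loess"], infl)
    print(f"cluster {c}: {len(labels[labels==c]):4d} genes, {kind:22s}"
          + (f" turning at {infl.extremum_age:.1f} years" if infl.is_interior else ""))

# 5. variance dysregulation in older adults
split = at.split_age_groups(cohort, low=10, mid=20)
matched = at.mean_match(logcpm[kept], split, tol=0.5)
vres = at.variance_ftest(logcpm[kept][matched], split, cohort)
g = at.global_variance_ttest(vres.var_young, vres.var_old,
                             n_young=len(split.group_young), n_old=len(split.group_old))
print(f"variance old vs young: t = {g['t']:.2f} (df={g['df']}), p = {g['p']:.2e}")
```

Output:

```
705 of 2000 genes (35.2%) change with age
cluster 1:   69 genes, nonlinear_u            turning at 9.4 years
cluster 2:  203 genes, linear_up
cluster 3:  154 genes, nonlinear_inverted_u   turning at 10.8 years
cluster 4:  279 genes, linear_down
variance old vs young: t = -6.82 (df=1604), p = 1.31e-11
```

The cohort planted 28% trend genes in four archetypes with interior extrema
at age 10 and extra old-age variance in 10% of genes: the pipeline calls
~35% (the 28% plus the documented anti-conservativeness of the
selection-then-test p-value, controlled at the BH level), recovers the four
shapes, dates the turns within ~1 year of truth, and the negative global t
says old-age variance is systematically higher.

Cluster 3 here mixes the planted inverted-U genes with false-positive flat
genes — at these effect sizes the inverted-U archetype (rising to age 10,
falling after) is dominated by its long declining limb, so expect it to
blend with linear-down on weaker data.

## Command line

```bash
agetrends simulate --seed 1 --n-genes 2000 --out data/
agetrends run-all --config config.yaml --seed 1 --out results/
```

Subcommands `simulate`, `preprocess`, `trajectory`, `dysregulation`,
`deconvolve`, `run-all`; the config is a YAML file overriding any default in
`agetrends.pipeline.default_config()`. Every run writes `manifest.json`
with the config, the seed and SHA-256 hashes of all outputs; identical
(config, seed) reruns are byte-identical.

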