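"""Count normalization, gene filtering, covariate residualization, and PCA.

The pipeline entry point is counts -> logCPM -> expression filter ->
(optional outlier screen) -> residualization of nuisance covariates ->
PCA with a per-component age association test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "compute_logcpm",
    "filter_genes",
    "residualize",
    "run_pca",
    "pc_association",
    "flag_outlier_samples",
    "PCAssociation",
]


def compute_logcpm(
    counts: pd.DataFrame,
    prior_count: float = 0.5,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """log2 counts-per-million with a small prior offset.

    entry = log2((count + prior) / (lib + 2*prior) * 1e6).  Library sizes
    default to the column sums of the matrix passed in; pass ``lib_sizes``
    (e.g. sums of the unfiltered matrix) to normalize a subset consistently.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts contain negative entries")
    if lib_sizes is None:
        lib = values.sum(axis=0)
    else:
        lib = lib_sizes.reindex(counts.columns).to_numpy(dtype=float)
    zero = np.flatnonzero(lib <= 0)
    if zero.size:
        bad = counts.columns[zero[0]]
        raise ValueError(f"sample {bad!r} has zero library size")
    logcpm = np.log2((values + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    out = pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)
    out.attrs["scale_tag"] = "logcpm"
    return out


def filter_genes(
    logcpm: pd.DataFrame, threshold: float = 4.0, min_samples: int = 15
) -> pd.Series:
    """Boolean mask of genes with logCPM strictly above ``threshold`` in at
    least ``min_samples`` samples (the expression filter used before any
    modeling)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_samples > logcpm.shape[1]:
        raise ValueError("min_samples exceeds number of samples")
    n_above = (logcpm.to_numpy() > threshold).sum(axis=1)
    mask = pd.Series(n_above >= min_samples, index=logcpm.index, name="retained")
    logger.info("gene filter: %d of %d genes retained", int(mask.sum()), len(mask))
    return mask


def _design_matrix(samples: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    missing = [c for c in covariates if c not in samples.columns]
    if missing:
        raise ValueError(f"covariates not in sample table: {missing}")
    parts = [pd.Series(1.0, index=samples.index, name="intercept")]
    for c in covariates:
        col = samples[c]
        if col.dtype.kind in "biufc":
            parts.append(col.astype(float))
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            parts.append(dummies)
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); columns: {list(X.columns)}"
        )
    return X


def residualize(
    expr: pd.DataFrame, samples: pd.DataFrame, covariates: list[str]
) -> pd.DataFrame:
    """Per-gene OLS residuals of expression on intercept + covariates.

    Categorical covariates are expanded to indicator columns.  Columns of
    ``expr`` must align with rows of ``samples`` (matched on sample_id).
    """
    samples = samples.set_index("sample_id").loc[list(expr.columns)].reset_index()
    X = _design_matrix(samples, covariates).to_numpy()
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    out = pd.DataFrame(resid, index=expr.index, columns=expr.columns)
    out.attrs["scale_tag"] = "residual"
    return out


def run_pca(expr: pd.DataFrame, n_components: int = 10):
    """PCA of sample expression profiles (genes are features, centered
    per gene).  Returns (scores sample x PC, variance-explained vector)."""
    n_samples = expr.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    if n_components > min(expr.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, samples)={min(expr.shape)}"
        )
    X = expr.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    score_df = pd.DataFrame(scores, index=expr.columns, columns=cols)
    return score_df, pca.explained_variance_ratio_


class PCAssociation:
    """Simple linear regression of a PC score on age."""

    def __init__(self, pc_index: int, beta: float, ci_low: float, ci_high: float, p_value: float):
        self.pc_index = pc_index
        self.beta = beta
        self.ci_low = ci_low
        self.ci_high = ci_high
        self.p_value = p_value

    def __repr__(self):
        return (
            f"PCAssociation(PC{self.pc_index}: beta={self.beta:.4g} "
            f"[{self.ci_low:.4g}, {self.ci_high:.4g}], p={self.p_value:.3g})"
        )


def pc_association(
    scores: pd.DataFrame, samples: pd.DataFrame, pc_index: int
) -> PCAssociation:
    """OLS of PC score on age with a normal-theory 95% CI and two-sided p."""
    col = f"PC{pc_index}"
    if col not in scores.columns:
        raise ValueError(f"PC index {pc_index} not among computed PCs")
    age = (
        samples.set_index("sample_id")
        .loc[list(scores.index), "age"]
        .to_numpy(dtype=float)
    )
    if np.ptp(age) == 0:
        raise ValueError("age column is constant; association undefined")
    X = sm.add_constant(age)
    fit = sm.OLS(scores[col].to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    return PCAssociation(
        pc_index=pc_index,
        beta=float(fit.params[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[1]),
    )


def flag_outlier_samples(
    logcpm: pd.DataFrame, marker_genes: list[str], z_threshold: float = 3.0
) -> pd.Series:
    """Marker-score screen for contaminated or aberrant samples.

    The score is the mean logCPM of a user-supplied marker set per sample;
    samples whose score sits more than ``z_threshold`` robust-z units from
    the cohort are flagged.  A simplified screen — the appropriate marker
    set (e.g. choroid-plexus markers for contamination) is the caller's
    responsibility.
    """
    present = [g for g in marker_genes if g in logcpm.index]
    if not present:
        raise ValueError("none of the marker genes are present in the matrix")
    score = logcpm.loc[present].mean(axis=0)
    z = (score - score.mean()) / score.std(ddof=1)
    flagged = z.abs() > z_threshold
    if flagged.any():
        logger.warning("flagged %d outlier sample(s): %s", int(flagged.sum()),
                       list(score.index[flagged]))
    return flagged
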