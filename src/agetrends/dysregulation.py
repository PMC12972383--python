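"""Age-stratified variance (dysregulation) testing.

Older adults are compared with younger adults on per-gene expression
variance: samples are split into a young-adult window [low, mid] and an old
group (> mid), genes are restricted to those with comparable mean expression
in the two groups, sex is regressed out, and each gene gets a two-sided
F-test on the residual variances with BH control.  A global paired t-test on
log variances across genes asks whether variance is systematically higher in
the old group — the transcriptome-wide dysregulation signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AgeGroupSplit",
    "split_age_groups",
    "mean_match",
    "variance_ftest",
    "global_variance_ttest",
]


@dataclass
class AgeGroupSplit:
    group_young: list  # sample ids with low <= age <= mid
    group_old: list  # sample ids with age > mid
    bounds: tuple


def split_age_groups(samples: pd.DataFrame, low: float = 10.0, mid: float = 20.0) -> AgeGroupSplit:
    """Partition samples into adult age bands: young = [low, mid], old = (mid, inf);
    samples younger than ``low`` are excluded."""
    if not low < mid:
        raise ValueError("low must be < mid")
    age = samples["age"].to_numpy(dtype=float)
    ids = samples["sample_id"].to_numpy()
    young = list(ids[(age >= low) & (age <= mid)])
    old = list(ids[age > mid])
    if not young or not old:
        raise ValueError(
            f"empty age group with bounds ({low}, {mid}): "
            f"{len(young)} young, {len(old)} old"
        )
    logger.info(
        "age split (%g, %g]: %d young, %d old, %d excluded",
        low, mid, len(young), len(old), len(ids) - len(young) - len(old),
    )
    return AgeGroupSplit(group_young=young, group_old=old, bounds=(low, mid))


def mean_match(expr: pd.DataFrame, split: AgeGroupSplit, tol: float = 0.5) -> pd.Series:
    """Genes whose group logCPM means differ by at most ``tol`` (inclusive) —
    the mean-expression control applied before variance testing."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    m_young = expr[split.group_young].mean(axis=1)
    m_old = expr[split.group_old].mean(axis=1)
    mask = (m_young - m_old).abs() <= tol
    mask.name = "mean_matched"
    logger.info("mean matching at tol=%g: %d of %d genes retained",
                tol, int(mask.sum()), len(mask))
    return mask


def _residualize_sex(expr: pd.DataFrame, samples: pd.DataFrame, sample_ids: list) -> np.ndarray:
    """One global per-gene OLS on a sex indicator across the included
    samples; returns residuals (genes x samples)."""
    meta = samples.set_index("sample_id").loc[sample_ids]
    sex = pd.get_dummies(meta["sex"], drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(sample_ids))] + [sex[c].to_numpy() for c in sex])
    Y = expr[sample_ids].to_numpy(dtype=float).T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return (Y - X @ beta).T


def variance_ftest(
    expr: pd.DataFrame,
    split: AgeGroupSplit,
    samples: pd.DataFrame,
    adjust_sex: bool = True,
) -> pd.DataFrame:
    """Two-sided per-gene F-test of old-group vs young-group variance.

    Sex is residualized across all included samples first (one global OLS
    per gene); variances use n_g - 1; f = var_old / var_young with df
    (n_old - 1, n_young - 1); two-sided p = 2*min(tail, 1 - tail) capped at
    1; BH q across tested genes.
    """
    ny, no = len(split.group_young), len(split.group_old)
    if ny < 3 or no < 3:
        raise ValueError(f"each group needs >= 3 samples (got {ny}, {no})")
    included = split.group_young + split.group_old
    if adjust_sex:
        resid = _residualize_sex(expr, samples, included)
    else:
        resid = expr[included].to_numpy(dtype=float)
    ry = resid[:, :ny]
    ro = resid[:, ny:]
    var_young = ry.var(axis=1, ddof=1)
    var_old = ro.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = var_old / var_young
    cdf = stats.f.cdf(f, no - 1, ny - 1)
    p = np.minimum(2 * np.minimum(cdf, 1 - cdf), 1.0)
    p = np.where(np.isfinite(f), p, 1.0)
    _, q, *_ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "var_young": var_young,
            "var_old": var_old,
            "f_stat": f,
            "p": p,
            "q": q,
            "direction": np.where(var_old >= var_young, "old_greater", "young_greater"),
        },
        index=expr.index,
    )


def global_variance_ttest(
    var_young: np.ndarray,
    var_old: np.ndarray,
    log_base: str = "natural",
    n_young: int | None = None,
    n_old: int | None = None,
) -> dict:
    """Paired t-test on log-transformed per-gene variances (pairs = genes).

    Reports t, df = n_genes - 1, two-sided p, the raw-scale mean variance of
    each group and the mean paired difference of log variances
    (young - old, so systematically higher old variance gives a negative t
    and a negative mean difference).  Genes with a zero variance in either
    group are dropped with a warning.

    When the group sample sizes are supplied, each log variance is centered
    by its small-sample bias E[ln(s^2/sigma^2)] = psi(k/2) - ln(k/2) with
    k = n_g - 1; without this, groups of unequal size differ systematically
    in E[ln s^2] even when the true variances are equal, which biases the
    paired test.
    """
    var_young = np.asarray(var_young, float)
    var_old = np.asarray(var_old, float)
    ok = (var_young > 0) & (var_old > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropping %d gene(s) with zero variance", dropped)
    vy, vo = var_young[ok], var_old[ok]
    if len(vy) < 2:
        raise ValueError("need >= 2 genes with positive variances in both groups")
    log = np.log if log_base == "natural" else np.log2
    scale = 1.0 if log_base == "natural" else 1.0 / np.log(2.0)

    def _lnvar_bias(n):
        k = n - 1
        return float(special.digamma(k / 2.0) - np.log(k / 2.0)) * scale

    correction = 0.0
    if n_young is not None and n_old is not None:
        correction = _lnvar_bias(n_young) - _lnvar_bias(n_old)
    diff = log(vy) - log(vo) - correction
    n = len(diff)
    mean_diff = float(diff.mean())
    sd = diff.std(ddof=1)
    if sd == 0:
        logger.warning("all paired log-variance differences identical; t undefined")
        t = 0.0
        p = 1.0
    else:
        t = mean_diff / (sd / np.sqrt(n))
        p = float(2 * stats.t.sf(abs(t), n - 1))
    return {
        "t": float(t),
        "df": n - 1,
        "p": p,
        "mean_var_young": float(vy.mean()),
        "mean_var_old": float(vo.mean()),
        "mean_log_diff": mean_diff,
        "log_base": log_base,
        "n_genes": n,
    }
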