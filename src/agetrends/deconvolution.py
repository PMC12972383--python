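"""Signature-based cell-type deconvolution and cell-corrected expression.

Bulk expression profiles are decomposed over a cell-type signature matrix by
nonnegative least squares with the coefficients renormalized to the simplex —
a deterministic, dependency-light estimator with the same contract as
support-vector deconvolution tools (nonnegative proportions from a
signature); outputs are labeled accordingly.  Estimated proportions are then
regressed on age per cell type, and expression can be residualized on sex +
proportions so the trajectory stage can be rerun free of composition effects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

METHOD_LABEL = "nnls-stand-in"  # recorded in outputs: NNLS, not CIBERSORTx

__all__ = [
    "build_signature",
    "estimate_proportions",
    "proportion_age_regression",
    "celltype_corrected_expression",
    "to_linear_cpm",
]


def build_signature(cell_profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cell-type x gene signature: per-type arithmetic mean expression on the
    linear scale, restricted to genes present in every profile, gene columns
    sorted for determinism.  Warns when the signature is ill-conditioned
    (near-duplicate cell-type profiles make proportions non-identifiable)."""
    if len(cell_profiles) < 2:
        raise ValueError("need >= 2 cell types to build a signature")
    shared = None
    for name, prof in cell_profiles.items():
        genes = set(prof.index)
        shared = genes if shared is None else shared & genes
    if not shared:
        raise ValueError("cell profiles share no genes")
    genes = sorted(shared)
    rows = {name: prof.loc[genes].mean(axis=1) for name, prof in cell_profiles.items()}
    sig = pd.DataFrame(rows).T
    sig = sig[genes]
    if (sig.to_numpy() < 0).any():
        raise ValueError("signature expression must be nonnegative")
    cond = np.linalg.cond(sig.to_numpy().T)
    if cond > 1e8:
        logger.warning(
            "signature condition number %.2g: cell-type profiles are nearly "
            "collinear, proportions may be non-identifiable", cond
        )
    return sig


def to_linear_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts -> linear counts-per-million (columns sum to 1e6)."""
    values = counts.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[np.flatnonzero(lib <= 0)[0]]
        raise ValueError(f"sample {bad!r} has zero library size")
    return pd.DataFrame(values / lib * 1e6, index=counts.index, columns=counts.columns)


def estimate_proportions(
    bulk: pd.DataFrame, signature: pd.DataFrame, input_scale: str = "counts"
) -> pd.DataFrame:
    """Per-sample NNLS of bulk linear-CPM on the signature columns, with the
    coefficients renormalized to sum to 1.

    ``input_scale``: "counts" converts the bulk matrix to CPM first; "cpm"
    uses it as-is.  Returns a sample x cell-type table with a
    ``residual_norm`` column and the estimator label in ``attrs``.
    """
    if input_scale == "counts":
        bulk_cpm = to_linear_cpm(bulk)
    elif input_scale == "cpm":
        bulk_cpm = bulk
    else:
        raise ValueError(f"unknown input_scale {input_scale!r}")
    shared = bulk_cpm.index.intersection(signature.columns)
    if len(shared) < 2 * signature.shape[0]:
        raise ValueError(
            f"only {len(shared)} shared genes for {signature.shape[0]} cell types"
        )
    A = signature[shared].to_numpy(dtype=float).T  # genes x cell types
    B = bulk_cpm.loc[shared].to_numpy(dtype=float)  # genes x samples
    n_types = A.shape[1]
    props = np.empty((B.shape[1], n_types))
    resid = np.empty(B.shape[1])
    for s in range(B.shape[1]):
        coef, rnorm = nnls(A, B[:, s])
        total = coef.sum()
        if total <= 0:
            logger.warning("sample %s: all-zero NNLS solution; uniform fallback",
                           bulk_cpm.columns[s])
            coef = np.full(n_types, 1.0 / n_types)
        else:
            coef = coef / total
        props[s] = coef
        resid[s] = rnorm
    out = pd.DataFrame(props, index=bulk_cpm.columns, columns=signature.index)
    out["residual_norm"] = resid
    out.attrs["method"] = METHOD_LABEL
    return out


def _proportion_columns(props: pd.DataFrame) -> list[str]:
    return [c for c in props.columns if c != "residual_norm"]


def proportion_age_regression(props: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type OLS of proportion on age: beta (proportion/yr),
    normal-theory 95% CI, two-sided p.  Constant proportions get beta 0,
    p 1 and a degeneracy warning."""
    if len(props) < 3:
        raise ValueError("need >= 3 samples")
    age = (
        samples.set_index("sample_id").loc[list(props.index), "age"].to_numpy(dtype=float)
    )
    X = sm.add_constant(age)
    rows = []
    for ct in _proportion_columns(props):
        y = props[ct].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.warning("cell type %s has constant proportions", ct)
            rows.append({"cell_type": ct, "beta": 0.0, "ci_low": 0.0,
                         "ci_high": 0.0, "p": 1.0})
            continue
        fit = sm.OLS(y, X).fit()
        ci = fit.conf_int(alpha=0.05)[1]
        rows.append(
            {
                "cell_type": ct,
                "beta": float(fit.params[1]),
                "ci_low": float(ci[0]),
                "ci_high": float(ci[1]),
                "p": float(fit.pvalues[1]),
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def celltype_corrected_expression(
    expr: pd.DataFrame,
    props: pd.DataFrame,
    samples: pd.DataFrame,
    extra_covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Residualize expression on intercept + sex (+ extra covariates) +
    cell-type proportions, dropping the largest-mean cell type's column to
    break the sum-to-one collinearity.  Output feeds the trajectory stage
    unchanged."""
    ids = list(expr.columns)
    if not set(ids) <= set(props.index):
        missing = sorted(set(ids) - set(props.index))
        raise ValueError(f"proportions missing for samples: {missing[:5]}")
    meta = samples.set_index("sample_id").loc[ids]
    ptab = props.loc[ids, _proportion_columns(props)]
    drop = ptab.mean(axis=0).idxmax()
    logger.info("dropping proportion column %r (largest mean) from the design", drop)
    kept = ptab.drop(columns=[drop])
    parts = [pd.Series(1.0, index=kept.index, name="intercept")]
    sex = pd.get_dummies(meta["sex"], prefix="sex", drop_first=True, dtype=float)
    parts.append(sex)
    if extra_covariates:
        for c in extra_covariates:
            col = meta[c]
            if col.dtype.kind in "biufc":
                parts.append(col.astype(float))
            else:
                parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
    parts.append(kept)
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient corrected design ({rank} < {X.shape[1]}); "
            f"columns: {list(X.columns)}"
        )
    Xv = X.to_numpy(dtype=float)
    Y = expr.to_numpy(dtype=float).T
    beta, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
    resid = (Y - Xv @ beta).T
    out = pd.DataFrame(resid, index=expr.index, columns=expr.columns)
    out.attrs["scale_tag"] = "residual"
    return out
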