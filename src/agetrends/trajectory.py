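"""Per-gene ARIMA trajectory modeling, trend calling, clustering and
inflection-age estimation.

Samples are placed on an equally spaced index in age order (rank space)
because ARMA likelihoods assume equal spacing; calendar age re-enters only
for LOESS smoothing and inflection estimation.  For each gene every order in
an :class:`~agetrends.arima.ArimaGrid` is fit by exact ML, the minimum-AIC
model is kept, and its trajectory is tested against the constant-mean
Gaussian null — either by a chi-square likelihood-ratio test (fast,
deterministic; mildly anti-conservative because the alternative was itself
AIC-selected) or by a permutation test that repeats the whole grid search on
age-shuffled series.  Benjamini-Hochberg control across genes yields the
trend-gene (DEG) set, whose fitted trajectories are Ward-clustered and
summarized per cluster with a LOESS curve from which the inflection age is
read off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .arima import ArimaGrid, ArmaFit, fit_arma, null_fit

logger = logging.getLogger(__name__)

__all__ = [
    "order_by_age",
    "TrajectoryFit",
    "fit_gene_arima",
    "trend_significance",
    "fit_trajectories",
    "call_degs",
    "cluster_trajectories",
    "loess_smooth",
    "summarize_cluster",
    "InflectionEstimate",
    "estimate_inflection",
    "classify_trajectory",
    "compare_deg_sets",
    "coefficient_correlation",
    "slope_summary",
]


# ---------------------------------------------------------------------------
# ordering and model selection
# ---------------------------------------------------------------------------


def order_by_age(samples: pd.DataFrame) -> pd.DataFrame:
    """Stable sort of the sample table by age, ties broken by sample_id."""
    if samples["age"].isna().any():
        bad = samples.loc[samples["age"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing age for samples: {bad}")
    out = samples.sort_values(["age", "sample_id"], kind="mergesort").reset_index(
        drop=True
    )
    return out


@dataclass
class TrajectoryFit:
    """Best ARIMA model for one gene plus its trend test."""

    gene_id: str
    order: tuple
    aic: float
    log_likelihood: float
    fitted: np.ndarray = field(repr=False)
    trend_p: float = np.nan
    trend_q: float = np.nan
    model: ArmaFit | None = field(default=None, repr=False)


def fit_gene_arima(series: np.ndarray, grid: ArimaGrid | None = None) -> ArmaFit:
    """Minimum-AIC exact-ML fit over the grid.

    Orders whose fit fails are dropped with a warning; AIC ties (within
    1e-9) break toward smaller p+d+q, then smaller d.  Raises if every
    order fails.
    """
    grid = grid or ArimaGrid()
    series = np.asarray(series, dtype=float)
    if len(series) < 10:
        raise ValueError("series must have length >= 10")
    best: ArmaFit | None = None
    for p, d, q in grid.orders():
        try:
            if (p, d, q) == (0, 0, 0) and grid.include_constant:
                fit = null_fit(series)
            else:
                fit = fit_arma(series, (p, d, q), with_mean=grid.include_constant and d == 0)
        except (ArithmeticError, np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("order (%d,%d,%d) failed to fit: %s", p, d, q, exc)
            continue
        if best is None:
            best = fit
        elif fit.aic < best.aic - 1e-9:
            best = fit
        elif abs(fit.aic - best.aic) <= 1e-9:
            bo, fo = best.order, fit.order
            if (sum(fo), fo[1]) < (sum(bo), bo[1]):
                best = fit
    if best is None:
        raise RuntimeError("all grid orders failed to converge")
    return best


def trend_significance(
    series: np.ndarray,
    best_fit: ArmaFit,
    method: str = "lrt",
    n_perm: int = 999,
    seed: int = 0,
    grid: ArimaGrid | None = None,
) -> float:
    """P-value of the selected trajectory against the constant-mean null.

    ``lrt``: chi-square on 2*(l_best - l_null); degrees of freedom are the
    parameter-count difference, floored at 1 (orders such as (0,1,0) have
    fewer parameters than the null).  Returns 1.0 when the null itself was
    selected.  ``permutation``: the entire grid search is repeated on
    ``n_perm`` age-shuffles and the observed AIC advantage over the null is
    ranked among the shuffled ones.
    """
    series = np.asarray(series, dtype=float)
    null = null_fit(series)
    if method == "lrt":
        if best_fit.order == (0, 0, 0):
            return 1.0
        stat = max(2.0 * (best_fit.loglik - null.loglik), 0.0)
        df = max(best_fit.k - null.k, 1)
        return float(stats.chi2.sf(stat, df))
    if method == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        grid = grid or ArimaGrid()
        rng = np.random.default_rng(seed)
        observed = null.aic - best_fit.aic
        hits = 0
        for _ in range(n_perm):
            shuffled = rng.permutation(series)
            perm_best = fit_gene_arima(shuffled, grid)
            perm_null = null_fit(shuffled)
            if perm_null.aic - perm_best.aic >= observed:
                hits += 1
        return (1.0 + hits) / (1.0 + n_perm)
    raise ValueError(f"unknown method {method!r}")


def fit_trajectories(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    grid: ArimaGrid | None = None,
    method: str = "lrt",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Grid-fit every gene of an expression matrix.

    Returns (per-gene results table, fitted-trajectory matrix over
    age-ordered samples, the age-ordered sample table).  Genes whose every
    grid order fails are excluded and logged.
    """
    grid = grid or ArimaGrid()
    ordered = order_by_age(samples)
    cols = list(ordered["sample_id"])
    mat = expr[cols].to_numpy(dtype=float)
    rows = []
    fitted_rows = []
    kept_genes = []
    for gi, gene in enumerate(expr.index):
        series = mat[gi]
        try:
            best = fit_gene_arima(series, grid)
        except RuntimeError as exc:
            logger.warning("gene %s excluded: %s", gene, exc)
            continue
        p = trend_significance(series, best, method=method, n_perm=n_perm,
                               seed=seed + gi, grid=grid)
        rows.append(
            {
                "gene_id": gene,
                "p": p,
                "order_p": best.order[0],
                "order_d": best.order[1],
                "order_q": best.order[2],
                "aic": best.aic,
                "loglik": best.loglik,
            }
        )
        fitted_rows.append(best.fittedvalues)
        kept_genes.append(gene)
    if not rows:
        raise RuntimeError("no gene could be fit")
    results = pd.DataFrame(rows).set_index("gene_id")
    fitted = pd.DataFrame(np.vstack(fitted_rows), index=kept_genes, columns=cols)
    ages = ordered["age"].to_numpy(dtype=float)
    results["slope_summary"] = slope_summary(fitted, ages)
    return results, fitted, ordered


def call_degs(pvalues: pd.Series, fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment; genes with q < fdr are the DEG set."""
    if len(pvalues) == 0:
        raise ValueError("empty p-value vector")
    p = pvalues.to_numpy(dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    _, q, *_ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({"p": p, "q": q, "is_deg": q < fdr}, index=pvalues.index)
    logger.info("DEG calling: %d of %d genes at q < %g", int(out.is_deg.sum()),
                len(out), fdr)
    return out


# ---------------------------------------------------------------------------
# clustering and summaries
# ---------------------------------------------------------------------------


def cluster_trajectories(fitted: pd.DataFrame, k: int = 4):
    """Ward clustering of z-scored fitted trajectories into k clusters.

    Returns (assignments Series with labels 1..k, linkage matrix).  Genes
    with a constant fitted vector are z-scored to zero.
    """
    if len(fitted) < k:
        raise ValueError(f"need at least k={k} genes, got {len(fitted)}")
    X = fitted.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    tree = linkage(Z, method="ward", metric="euclidean")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return pd.Series(labels, index=fitted.index, name="cluster"), tree


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial (LOESS) smoother with tricube weights.

    At each grid point the ``ceil(span * n)`` nearest observations get
    tricube weights and a degree-``degree`` weighted polynomial is fit;
    exact on polynomials up to that degree.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    grid = np.asarray(grid, float)
    n = len(x)
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    out = np.empty(len(grid))
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    for i, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argpartition(d, k - 1)[:k]
        dk = d[idx]
        h = dk.max()
        if h <= 0:
            w = np.ones(k)
        else:
            w = (1.0 - np.minimum(dk / h, 1.0) ** 3) ** 3
            if w.sum() <= 0:
                w = np.ones(k)
        dx = xs[idx] - g
        X = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys[idx] * sw, rcond=None)
        out[i] = beta[0]
    return out


def summarize_cluster(
    member_fitted: pd.DataFrame,
    ages: np.ndarray,
    loess_span: float = 0.75,
    grid_step: float = 0.1,
) -> dict:
    """Pointwise mean and sd of member trajectories plus a LOESS curve of
    the mean over a dense age grid."""
    if len(member_fitted) == 0:
        raise ValueError("empty cluster")
    ages = np.asarray(ages, float)
    X = member_fitted.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    grid = np.arange(ages.min(), ages.max() + grid_step / 2, grid_step)
    curve = loess_smooth(ages, mean, grid, span=loess_span, degree=2)
    return {"ages": ages, "mean": mean, "sd": sd, "age_grid": grid, "loess": curve}


# ---------------------------------------------------------------------------
# inflection and classification
# ---------------------------------------------------------------------------


@dataclass
class InflectionEstimate:
    extremum_age: float
    extremum_type: str  # "minimum" | "maximum"
    is_interior: bool


def estimate_inflection(
    age_grid: np.ndarray, curve: np.ndarray, margin: float = 1.0
) -> InflectionEstimate:
    """Age of the dominant extremum of a smoothed trajectory.

    Both the minimum and the maximum of the curve are located; the one that
    deviates more (in expression units) from the straight chord between the
    curve's endpoints is reported.  Ties break toward the younger age.  A
    numerically flat curve is reported as a non-interior minimum at the
    youngest age.
    """
    age_grid = np.asarray(age_grid, float)
    curve = np.asarray(curve, float)
    if len(age_grid) < 3:
        raise ValueError("grid must have >= 3 points")
    lo, hi = age_grid[0], age_grid[-1]
    if np.ptp(curve) < 1e-10:
        return InflectionEstimate(extremum_age=float(lo), extremum_type="minimum",
                                  is_interior=False)
    chord = curve[0] + (curve[-1] - curve[0]) * (age_grid - lo) / (hi - lo)
    imin = int(np.argmin(curve))  # argmin/argmax take the first (youngest) tie
    imax = int(np.argmax(curve))
    dev_min = abs(curve[imin] - chord[imin])
    dev_max = abs(curve[imax] - chord[imax])
    if dev_min > dev_max or (dev_min == dev_max and age_grid[imin] <= age_grid[imax]):
        i, kind = imin, "minimum"
    else:
        i, kind = imax, "maximum"
    age = float(age_grid[i])
    interior = (age >= lo + margin) and (age <= hi - margin)
    return InflectionEstimate(extremum_age=age, extremum_type=kind, is_interior=interior)


def classify_trajectory(curve: np.ndarray, inflection: InflectionEstimate) -> str:
    """Archetype of a cluster summary curve.

    Interior extremum -> nonlinear (minimum = U, maximum = inverted U);
    otherwise the sign of the endpoint difference gives the linear label.
    """
    if inflection.is_interior:
        return "nonlinear_u" if inflection.extremum_type == "minimum" else "nonlinear_inverted_u"
    return "linear_up" if curve[-1] >= curve[0] else "linear_down"


# ---------------------------------------------------------------------------
# run comparison
# ---------------------------------------------------------------------------


def compare_deg_sets(set_a, set_b) -> dict:
    """Overlap fraction |A∩B|/|A| and Jaccard index of two DEG sets."""
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("reference DEG set is empty")
    inter = len(a & b)
    union = len(a | b)
    return {"overlap": inter / len(a), "jaccard": inter / union if union else 0.0}


def slope_summary(fitted: pd.DataFrame, ages: np.ndarray) -> np.ndarray:
    """Per-gene endpoint slope of the fitted trajectory: (last - first) /
    age span — the scalar effect-size summary used to compare runs."""
    ages = np.asarray(ages, float)
    span = ages[-1] - ages[0]
    if span <= 0:
        raise ValueError("age span is zero")
    X = fitted.to_numpy(dtype=float)
    return (X[:, -1] - X[:, 0]) / span


def coefficient_correlation(
    fitted_a: pd.DataFrame, fitted_b: pd.DataFrame, ages_a: np.ndarray, ages_b: np.ndarray
) -> float:
    """Pearson correlation of per-gene trajectory slopes between two runs,
    over their shared genes."""
    shared = fitted_a.index.intersection(fitted_b.index)
    if len(shared) == 0:
        raise ValueError("no shared genes between the two runs")
    sa = slope_summary(fitted_a.loc[shared], ages_a)
    sb = slope_summary(fitted_b.loc[shared], ages_b)
    if len(shared) < 2:
        raise ValueError("need >= 2 shared genes for a correlation")
    return float(stats.pearsonr(sa, sb)[0])
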