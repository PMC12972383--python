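"""Synthetic lifespan cohorts with known ground truth.

Generates a cross-sectional cohort (ages, sexes, batches), per-gene counts
with planted age trajectories, and bulk mixtures of a cell-type signature
with planted proportion drift.  Defaults emulate the study conditions this
package targets: ~88 hippocampus samples spanning 3-35 years, ~28% of genes
carrying an age trend split across four archetypes (linear up/down and
U / inverted-U with an interior extremum at ~10 years), inflated expression
variance after age 20, and oligodendrocyte / glutamatergic-neuron
proportions drifting with age.

Noise model: a gene's log2 expression is Gaussian around its archetype
trajectory (sd = ``dispersion``, multiplied by ``old_var_inflation`` past
the age-20 switch); the latent log2-CPM value is converted to an expected
count given the sample's library size and the observed count is drawn
negative-binomially around that expectation (gamma-Poisson with a small
count-level dispersion).  Downstream analyses operate on logCPM, so the
log-scale Gaussian is the variance component the variance tests see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARCHETYPES = ("flat", "linear_up", "linear_down", "u_shape", "inverted_u")

#: fraction of trend genes assigned to each archetype; mirrors the observed
#: cluster shares among age-associated genes (linear up 37.9%, linear down
#: 43.9%, U-shaped 12.3%, inverted-U 5.9%).
ARCHETYPE_SHARES = {
    "linear_up": 0.379,
    "linear_down": 0.439,
    "u_shape": 0.123,
    "inverted_u": 0.059,
}

OLD_AGE_CUTOFF = 20.0  # years; hard switch for variance inflation


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated cross-sectional cohort."""

    n_samples: int = 88
    age_range: tuple = (3.0, 35.0)
    sex_ratio: float = 55 / 88  # fraction female, as in the 88-sample cohort
    n_batches: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ConfigError("n_samples must be >= 4")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError("age_range min must be < max")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must be in [0, 1]")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")


@dataclass
class GeneTruth:
    """Planted trajectory for one gene.

    ``slope`` is logCPM per year for linear archetypes and the quadratic
    curvature (logCPM per year^2) for u_shape / inverted_u, whose trajectory
    is ``base_mean +/- slope * (age - inflection_age)^2`` so that base_mean
    is the expression at the extremum.  ``dispersion`` is the log2-scale
    Gaussian sd; ``old_var_inflation`` multiplies it for samples older than
    20 years.
    """

    gene_id: str
    archetype: str = "flat"
    base_mean: float = 7.0
    slope: float = 0.0
    inflection_age: float | None = None
    dispersion: float = 0.5
    old_var_inflation: float = 1.0

    def __post_init__(self):
        if self.archetype not in ARCHETYPES:
            raise ConfigError(f"unknown archetype {self.archetype!r}")
        if self.dispersion <= 0:
            raise ConfigError(f"gene {self.gene_id}: dispersion must be > 0")
        if self.old_var_inflation < 1.0:
            raise ConfigError(f"gene {self.gene_id}: old_var_inflation must be >= 1")
        if self.archetype in ("u_shape", "inverted_u") and self.inflection_age is None:
            raise ConfigError(
                f"gene {self.gene_id}: nonlinear archetype requires inflection_age"
            )


@dataclass
class MixtureTruth:
    """Cell-type signature plus planted proportion drift.

    ``signature``: cell-type x gene mean expression on the linear CPM scale.
    ``baseline_proportions``: per-type fractions at the midpoint age.
    ``proportion_slopes``: per-type change in proportion per year.
    """

    signature: pd.DataFrame
    baseline_proportions: pd.Series
    proportion_slopes: pd.Series

    def __post_init__(self):
        if self.signature.shape[0] < 2:
            raise ConfigError("signature must have >= 2 cell types")
        if (self.baseline_proportions < 0).any():
            raise ConfigError("baseline_proportions must be >= 0")
        total = float(self.baseline_proportions.sum())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError("baseline_proportions must sum to 1")
        if not self.signature.index.equals(self.baseline_proportions.index):
            raise ConfigError("signature / baseline_proportions cell types differ")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Sample table with columns sample_id, age, sex, batch.

    Ages are uniform over ``age_range`` at 0.1-year resolution; the number of
    females is ``round(sex_ratio * n)`` and sexes are assigned in a seeded
    random order; batches are assigned round-robin.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    lo, hi = config.age_range
    ages = np.round(rng.uniform(lo, hi, size=n), 1)
    n_female = int(round(config.sex_ratio * n))
    sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sex)
    batch = np.array([f"batch{i % config.n_batches + 1}" for i in range(n)])
    width = max(3, len(str(n)))
    sample_id = [f"s{i + 1:0{width}d}" for i in range(n)]
    return pd.DataFrame(
        {"sample_id": sample_id, "age": ages, "sex": sex, "batch": batch}
    )


# ---------------------------------------------------------------------------
# gene-level counts
# ---------------------------------------------------------------------------


def trajectory_mean(truth: GeneTruth, ages: np.ndarray, age_mid: float) -> np.ndarray:
    """Planted mean log2 expression over ``ages``."""
    ages = np.asarray(ages, dtype=float)
    if truth.archetype == "flat":
        trend = np.zeros_like(ages)
    elif truth.archetype == "linear_up":
        trend = abs(truth.slope) * (ages - age_mid)
    elif truth.archetype == "linear_down":
        trend = -abs(truth.slope) * (ages - age_mid)
    elif truth.archetype == "u_shape":
        trend = abs(truth.slope) * (ages - truth.inflection_age) ** 2
    else:  # inverted_u
        trend = -abs(truth.slope) * (ages - truth.inflection_age) ** 2
    return truth.base_mean + trend


def _nb_draw(rng: np.random.Generator, lam: np.ndarray, nb_dispersion: float):
    """Negative-binomial draws with mean lam and var lam + nb_dispersion*lam^2."""
    lam = np.maximum(lam, 1e-12)
    if nb_dispersion <= 1e-12:
        return rng.poisson(lam)
    size = 1.0 / nb_dispersion
    return rng.poisson(rng.gamma(shape=size, scale=lam / size))


def simulate_counts(
    samples: pd.DataFrame,
    truths: list[GeneTruth],
    lib_size_mean: float = 1_000_000,
    seed: int = 0,
    nb_dispersion: float = 0.01,
    age_mid: float | None = None,
    batch_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x sample count matrix with planted trajectories.

    Returns (counts, truth table).  ``age_mid`` defaults to the midpoint of
    the observed age span; linear trends are centered there so base_mean is
    the expression at the middle of the lifespan.  ``batch_sd`` > 0 adds an
    independent per-gene, per-batch log2 offset of that sd — a simple
    technical batch effect for exercising covariate residualization.
    """
    if not truths:
        raise ConfigError("truths must contain at least one gene")
    if lib_size_mean <= 0:
        raise ConfigError("lib_size_mean must be > 0")
    rng = np.random.default_rng(seed)
    ages = samples["age"].to_numpy(dtype=float)
    n = len(ages)
    if age_mid is None:
        age_mid = 0.5 * (ages.min() + ages.max())
    old = ages > OLD_AGE_CUTOFF

    batches = pd.Categorical(samples["batch"])
    batch_idx = batches.codes
    n_batches = len(batches.categories)

    lib = lib_size_mean * rng.uniform(0.7, 1.3, size=n)
    counts = np.empty((len(truths), n), dtype=np.int64)
    for gi, tr in enumerate(truths):
        mu = trajectory_mean(tr, ages, age_mid)
        if batch_sd > 0:
            mu = mu + rng.normal(0.0, batch_sd, size=n_batches)[batch_idx]
        sd = tr.dispersion * np.where(old, tr.old_var_inflation, 1.0)
        latent = mu + rng.normal(0.0, 1.0, size=n) * sd
        lam = np.exp2(latent) / 1e6 * lib
        counts[gi] = _nb_draw(rng, lam, nb_dispersion)

    gene_ids = [tr.gene_id for tr in truths]
    if len(set(gene_ids)) != len(gene_ids):
        raise ConfigError("duplicate gene_id in truths")
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples["sample_id"])
    truth_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "archetype": [tr.archetype for tr in truths],
            "base_mean": [tr.base_mean for tr in truths],
            "slope": [tr.slope for tr in truths],
            "inflection_age": [tr.inflection_age for tr in truths],
            "dispersion": [tr.dispersion for tr in truths],
            "old_var_inflation": [tr.old_var_inflation for tr in truths],
        }
    ).set_index("gene_id")
    return counts_df, truth_df


def default_gene_truths(
    n_genes: int = 2000,
    signal_fraction: float = 0.28,
    seed: int = 0,
    age_range: tuple = (3.0, 35.0),
    inflection_age: float = 10.0,
    dispersion: float = 0.5,
    var_inflation: float = 1.5,
    var_inflation_fraction: float = 0.10,
) -> list[GeneTruth]:
    """Default gene truth table emulating the study conditions.

    28% of genes carry an age trend, split across the four archetypes in the
    observed cluster shares; nonlinear archetypes place their extremum at
    ~10 years; 10% of genes get 1.5x log-scale noise inflation past age 20.
    Linear slopes are 0.03-0.06 logCPM/yr, curvatures 0.002-0.005 logCPM/yr^2
    — effect sizes that give trajectories 1-2.5 log2 units of range over the
    3-35-year lifespan against a log-scale noise sd of 0.5.
    """
    rng = np.random.default_rng(seed)
    n_signal = int(round(signal_fraction * n_genes))
    kinds = ["flat"] * (n_genes - n_signal)
    shares = list(ARCHETYPE_SHARES.items())
    counts = [int(round(f * n_signal)) for _, f in shares]
    counts[0] += n_signal - sum(counts)  # absorb rounding in the largest class
    for (arch, _), c in zip(shares, counts):
        kinds += [arch] * c
    rng.shuffle(kinds)

    n_inflated = int(round(var_inflation_fraction * n_genes))
    inflated = np.zeros(n_genes, dtype=bool)
    inflated[rng.choice(n_genes, size=n_inflated, replace=False)] = True

    width = len(str(n_genes))
    truths = []
    for i, arch in enumerate(kinds):
        base = float(np.clip(rng.normal(7.0, 1.2), 5.0, 12.0))
        if arch in ("linear_up", "linear_down"):
            slope = rng.uniform(0.03, 0.06)
            infl = None
        elif arch in ("u_shape", "inverted_u"):
            slope = rng.uniform(0.002, 0.005)
            infl = inflection_age
        else:
            slope = 0.0
            infl = None
        truths.append(
            GeneTruth(
                gene_id=f"g{i + 1:0{width}d}",
                archetype=arch,
                base_mean=base,
                slope=float(slope),
                inflection_age=infl,
                dispersion=dispersion,
                old_var_inflation=var_inflation if inflated[i] else 1.0,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# cell-type mixtures
# ---------------------------------------------------------------------------


def true_proportions(
    samples: pd.DataFrame, mix: MixtureTruth, age_mid: float | None = None
) -> pd.DataFrame:
    """Per-sample planted proportions: baseline + slope*(age - age_mid),
    clipped to [0, 1] and renormalized to sum to 1."""
    ages = samples["age"].to_numpy(dtype=float)
    if age_mid is None:
        age_mid = 0.5 * (ages.min() + ages.max())
    base = mix.baseline_proportions.to_numpy(dtype=float)
    slopes = mix.proportion_slopes.reindex(mix.baseline_proportions.index).to_numpy(
        dtype=float
    )
    props = base[None, :] + slopes[None, :] * (ages - age_mid)[:, None]
    props = np.clip(props, 0.0, 1.0)
    props /= props.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        props, index=samples["sample_id"], columns=mix.baseline_proportions.index
    )


def simulate_mixture(
    samples: pd.DataFrame,
    mix: MixtureTruth,
    seed: int = 0,
    lib_size_mean: float = 1_000_000,
    nb_dispersion: float = 0.01,
    proportion_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk counts mixed from the signature plus the true proportion matrix.

    ``proportion_noise_sd`` adds per-sample compositional scatter (Gaussian
    jitter, clipped and renormalized) around the age-drifted baseline; with
    the default 0 the true proportions are an exact function of age.  The
    returned proportion matrix is the realized (possibly jittered) truth.
    """
    rng = np.random.default_rng(seed)
    props = true_proportions(samples, mix)
    if proportion_noise_sd > 0:
        vals = props.to_numpy() + rng.normal(0.0, proportion_noise_sd,
                                             size=props.shape)
        vals = np.clip(vals, 0.0, None)
        vals /= vals.sum(axis=1, keepdims=True)
        props = pd.DataFrame(vals, index=props.index, columns=props.columns)
    sig = mix.signature.to_numpy(dtype=float)  # cell types x genes
    expected_cpm = props.to_numpy() @ sig  # samples x genes
    n = len(samples)
    lib = lib_size_mean * rng.uniform(0.7, 1.3, size=n)
    lam = expected_cpm / 1e6 * lib[:, None]
    counts = _nb_draw(rng, lam, nb_dispersion).T  # genes x samples
    counts_df = pd.DataFrame(
        counts, index=mix.signature.columns, columns=samples["sample_id"]
    )
    return counts_df, props


def default_mixture_truth(n_genes: int = 500, seed: int = 0) -> MixtureTruth:
    """Six-cell-type mixture emulating the observed proportion drift.

    Oligodendrocytes gain +0.00099 proportion/yr and glutamatergic neurons
    lose -0.0017/yr (the two significant drifts in the study); the remainder
    is spread over the other types so slopes sum to zero and renormalization
    is a no-op within the age range.  Each cell type gets a block of
    enriched marker genes so the signature is well conditioned.
    """
    rng = np.random.default_rng(seed)
    types = [
        "oligodendrocyte",
        "glutamatergic_neuron",
        "astrocyte",
        "gabaergic_neuron",
        "microglia",
        "opc",
    ]
    baseline = pd.Series(
        [0.22, 0.33, 0.16, 0.12, 0.09, 0.08], index=types, name="baseline"
    )
    resid = -(0.00099 - 0.0017)  # spread so that all slopes sum to 0
    slopes = pd.Series(
        [0.00099, -0.0017] + [resid / 4] * 4, index=types, name="slope"
    )
    genes = [f"g{i + 1:0{len(str(n_genes))}d}" for i in range(n_genes)]
    expr = np.exp(rng.normal(3.0, 1.0, size=(len(types), n_genes)))
    block = n_genes // (2 * len(types))  # marker block per type
    for t in range(len(types)):
        cols = slice(t * block, (t + 1) * block)
        expr[t, cols] *= 20.0
    expr = expr / expr.sum(axis=1, keepdims=True) * 1e6  # CPM scale per type
    signature = pd.DataFrame(expr, index=types, columns=genes)
    return MixtureTruth(
        signature=signature, baseline_proportions=baseline, proportion_slopes=slopes
    )
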