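"""Pipeline orchestration: config, stage execution, provenance manifest.

A single config (YAML-loadable dict) drives the stages
simulate -> preprocess -> trajectory -> dysregulation -> deconvolve.
Every output table is TSV; a manifest JSON records the config, the seed,
package versions and the SHA-256 of each written file, so reruns can be
checked for byte identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arima import ArimaGrid
from . import deconvolution as deconv
from . import dysregulation as dysreg
from . import io as aio
from . import preprocess as prep
from . import simulate as sim
from . import trajectory as traj

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Demo configuration: a 2,000-gene x 88-sample synthetic cohort run
    through every stage with the documented defaults."""
    return {
        "seed": 0,
        "counts": None,  # path to a counts TSV/MTX; None -> simulate
        "metadata": None,
        "signature": None,  # path to a cell-type x gene signature TSV
        "stages": {
            "preprocess": True,
            "trajectory": True,
            "dysregulation": True,
            "deconvolve": True,
        },
        "simulate": {
            "n_samples": 88,
            "n_genes": 2000,
            "age_range": [3.0, 35.0],
            "sex_ratio": 55 / 88,
            "n_batches": 4,
            "signal_fraction": 0.28,
            "lib_size_mean": 1_000_000,
            "mixture_genes": 500,
        },
        "preprocess": {
            "prior_count": 0.5,
            "threshold": 4.0,
            "min_samples": 15,
            "covariates": ["sex", "batch"],
            "n_pcs": 10,
        },
        "trajectory": {
            "p_values": [0, 1, 2],
            "d_values": [0, 1],
            "q_values": [0, 1, 2],
            "method": "lrt",
            "n_perm": 999,
            "fdr": 0.05,
            "k": 4,
            "loess_span": 0.75,
            "margin": 1.0,
        },
        "dysregulation": {"low": 10.0, "mid": 20.0, "tol": 0.5, "fdr": 0.05},
        "deconvolve": {"correct": True},
    }


def _merge(base: dict, override: dict) -> dict:
    out = deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Writer:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: list[Path] = []

    def table(self, df: pd.DataFrame, name: str):
        path = self.out_dir / name
        aio.write_table(df, path)
        self.files.append(path)

    def manifest(self, config: dict) -> dict:
        man = {
            "package": "agetrends",
            "version": __version__,
            "seed": config["seed"],
            "config": config,
            "files": {
                str(p.relative_to(self.out_dir)): _sha256(p) for p in sorted(self.files)
            },
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(man, indent=2, sort_keys=True, default=str) + "\n")
        return man


def run_pipeline(config: dict | None = None, out_dir="results") -> dict:
    """Execute the enabled stages and return the provenance manifest."""
    cfg = _merge(default_config(), config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    w = _Writer(out_dir)
    seed = int(cfg["seed"])

    # ------------------------------------------------------------------ data
    if cfg["counts"] is None:
        scfg = cfg["simulate"]
        cohort = sim.CohortConfig(
            n_samples=int(scfg["n_samples"]),
            age_range=tuple(scfg["age_range"]),
            sex_ratio=float(scfg["sex_ratio"]),
            n_batches=int(scfg["n_batches"]),
            seed=seed,
        )
        samples = sim.simulate_cohort(cohort)
        truths = sim.default_gene_truths(
            n_genes=int(scfg["n_genes"]),
            signal_fraction=float(scfg["signal_fraction"]),
            seed=seed,
            age_range=tuple(scfg["age_range"]),
        )
        counts, truth_df = sim.simulate_counts(
            samples, truths, lib_size_mean=float(scfg["lib_size_mean"]), seed=seed + 1
        )
        w.table(counts, "counts.tsv")
        w.table(samples.set_index("sample_id"), "metadata.tsv")
        w.table(truth_df, "truth.tsv")
        logger.info("simulated %d genes x %d samples", *counts.shape)
    else:
        counts = aio.read_counts(cfg["counts"])
        samples = aio.read_metadata(cfg["metadata"])

    # ------------------------------------------------------------ preprocess
    pcfg = cfg["preprocess"]
    logcpm = prep.compute_logcpm(counts, prior_count=float(pcfg["prior_count"]))
    mask = prep.filter_genes(
        logcpm, threshold=float(pcfg["threshold"]), min_samples=int(pcfg["min_samples"])
    )
    logcpm = logcpm[mask]
    resid = prep.residualize(logcpm, samples, list(pcfg["covariates"]))
    n_pcs = min(int(pcfg["n_pcs"]), min(resid.shape) - 1)
    scores, varexp = prep.run_pca(resid, n_components=n_pcs)
    assoc = [
        prep.pc_association(scores, samples, i + 1).__dict__ for i in range(n_pcs)
    ]
    w.table(logcpm, "filtered_logcpm.tsv")
    w.table(resid, "residual_expr.tsv")
    w.table(scores, "pca_scores.tsv")
    w.table(pd.DataFrame(assoc).set_index("pc_index"), "pc_age_association.tsv")
    # ------------------------------------------------------------ trajectory
    results = fitted = ordered = None
    if cfg["stages"].get("trajectory", True):
        tcfg = cfg["trajectory"]
        grid = ArimaGrid(
            p_values=tuple(tcfg["p_values"]),
            d_values=tuple(tcfg["d_values"]),
            q_values=tuple(tcfg["q_values"]),
        )
        results, fitted, ordered = traj.fit_trajectories(
            resid, samples, grid=grid, method=tcfg["method"],
            n_perm=int(tcfg["n_perm"]), seed=seed,
        )
        degs = traj.call_degs(results["p"], fdr=float(tcfg["fdr"]))
        results = results.join(degs[["q", "is_deg"]])
        deg_genes = results.index[results["is_deg"]]
        ages = ordered["age"].to_numpy(dtype=float)
        if len(deg_genes) >= int(tcfg["k"]):
            labels, _ = traj.cluster_trajectories(fitted.loc[deg_genes], k=int(tcfg["k"]))
            results["cluster"] = labels.reindex(results.index)
            summaries = []
            inflections = []
            for c in sorted(labels.unique()):
                members = labels.index[labels == c]
                summ = traj.summarize_cluster(
                    fitted.loc[members], ages, loess_span=float(tcfg["loess_span"])
                )
                infl = traj.estimate_inflection(
                    summ["age_grid"], summ["loess"], margin=float(tcfg["margin"])
                )
                kind = traj.classify_trajectory(summ["loess"], infl)
                summaries.append(
                    pd.DataFrame(
                        {
                            "cluster": c,
                            "age": summ["age_grid"],
                            "loess": summ["loess"],
                        }
                    )
                )
                inflections.append(
                    {
                        "cluster": c,
                        "n_genes": len(members),
                        "extremum_age": infl.extremum_age,
                        "extremum_type": infl.extremum_type,
                        "is_interior": infl.is_interior,
                        "classification": kind,
                    }
                )
            w.table(pd.concat(summaries).set_index("cluster"), "cluster_curves.tsv")
            w.table(pd.DataFrame(inflections).set_index("cluster"), "inflections.tsv")
        w.table(results, "gene_results.tsv")
        w.table(fitted, "fitted_trajectories.tsv")

    # --------------------------------------------------------- dysregulation
    if cfg["stages"].get("dysregulation", True):
        dcfg = cfg["dysregulation"]
        split = dysreg.split_age_groups(samples, low=float(dcfg["low"]), mid=float(dcfg["mid"]))
        matched = dysreg.mean_match(logcpm, split, tol=float(dcfg["tol"]))
        vres = dysreg.variance_ftest(resid[matched], split, samples)
        gres = dysreg.global_variance_ttest(
            vres["var_young"].to_numpy(), vres["var_old"].to_numpy(),
            n_young=len(split.group_young), n_old=len(split.group_old),
        )
        w.table(vres, "variance_per_gene.tsv")
        w.table(pd.DataFrame([gres]).set_index("n_genes"), "variance_global.tsv")

    # ------------------------------------------------------------ deconvolve
    if cfg["stages"].get("deconvolve", True):
        if cfg["signature"] is not None:
            signature = aio.read_table(cfg["signature"])
            bulk = counts
        else:
            # demo route: a mixture cohort over the same samples, deconvolved
            # against the signature that generated it
            mix = sim.default_mixture_truth(
                n_genes=int(cfg["simulate"]["mixture_genes"]), seed=seed
            )
            signature = mix.signature
            bulk, true_props = sim.simulate_mixture(samples, mix, seed=seed + 2)
            w.table(true_props, "true_proportions.tsv")
        props = deconv.estimate_proportions(bulk, signature)
        trends = deconv.proportion_age_regression(props, samples)
        w.table(props, "proportions.tsv")
        w.table(trends, "proportion_trends.tsv")
        if cfg["deconvolve"].get("correct", True) and results is not None:
            corrected = deconv.celltype_corrected_expression(logcpm, props, samples)
            tcfg = cfg["trajectory"]
            grid = ArimaGrid(
                p_values=tuple(tcfg["p_values"]),
                d_values=tuple(tcfg["d_values"]),
                q_values=tuple(tcfg["q_values"]),
            )
            cres, cfit, cord = traj.fit_trajectories(
                corrected, samples, grid=grid, method=tcfg["method"],
                n_perm=int(tcfg["n_perm"]), seed=seed,
            )
            cdegs = traj.call_degs(cres["p"], fdr=float(tcfg["fdr"]))
            cres = cres.join(cdegs[["q", "is_deg"]])
            w.table(cres, "corrected_gene_results.tsv")
            degs_a = set(results.index[results["is_deg"]])
            degs_b = set(cres.index[cres["is_deg"]])
            if degs_a:
                cmp_stats = traj.compare_deg_sets(degs_a, degs_b)
                cmp_stats["coefficient_r"] = traj.coefficient_correlation(
                    fitted, cfit,
                    ordered["age"].to_numpy(float), cord["age"].to_numpy(float),
                )
                w.table(
                    pd.DataFrame([cmp_stats], index=["uncorrected_vs_corrected"]),
                    "deg_set_comparison.tsv",
                )

    return w.manifest(cfg)


def setup_logging(level: str = "INFO"):
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        stream=sys.stderr,
    )
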