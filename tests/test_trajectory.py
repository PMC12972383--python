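"""Trend calling, clustering, LOESS summaries and inflection estimation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import agetrends as at
from agetrends.arima import fit_arma, null_fit
from agetrends.trajectory import slope_summary


class TestOrderByAge:
    def test_ties_broken_by_sample_id(self):
        samples = pd.DataFrame(
            {"sample_id": ["c", "b", "a"], "age": [5.0, 3.0, 3.0],
             "sex": ["F"] * 3, "batch": ["b"] * 3}
        )
        out = at.order_by_age(samples)
        assert list(out.sample_id) == ["a", "b", "c"]

    def test_sorted_input_is_identity(self, toy_samples):
        out = at.order_by_age(toy_samples)
        assert list(out.sample_id) == list(toy_samples.sample_id)

    def test_invariant_to_input_permutation(self, toy_samples, rng):
        shuffled = toy_samples.sample(frac=1, random_state=0)
        a = at.order_by_age(toy_samples)
        b = at.order_by_age(shuffled)
        assert list(a.sample_id) == list(b.sample_id)

    def test_missing_age_rejected(self, toy_samples):
        samples = toy_samples.copy()
        samples.loc[2, "age"] = np.nan
        with pytest.raises(ValueError, match="age"):
            at.order_by_age(samples)


class TestTrendSignificance:
    def test_null_best_model_has_p_one(self, rng):
        y = rng.normal(size=40)
        assert at.trend_significance(y, null_fit(y)) == 1.0

    def test_permutation_minimum_p_on_strong_ramp(self):
        y = 0.1 * np.arange(60)
        fit = at.fit_gene_arima(y + np.random.default_rng(0).normal(size=60) * 0.05)
        p = at.trend_significance(y, fit, method="permutation", n_perm=99, seed=1)
        assert p <= 0.01  # 1/(1+99) is the smallest attainable value

    def test_permutation_needs_positive_n_perm(self, rng):
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="n_perm"):
            at.trend_significance(y, at.fit_gene_arima(y), method="permutation", n_perm=0)

    def test_lrt_inflation_is_bounded(self, rng):
        """The chi-square LRT applied to the AIC-selected model is known to be
        anti-conservative (the alternative was chosen for fitting well); the
        simulated null rejection rate at alpha=0.05 sits around 0.25 for the
        default 18-order grid and must stay inside (0.05, 0.35)."""
        ps = []
        for _ in range(400):
            y = rng.normal(size=88)
            ps.append(at.trend_significance(y, at.fit_gene_arima(y)))
        rate = np.mean(np.array(ps) < 0.05)
        assert 0.05 < rate < 0.35

    def test_unknown_method_rejected(self, rng):
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="method"):
            at.trend_significance(y, at.fit_gene_arima(y), method="bootstrap")


class TestCallDegs:
    def test_bh_by_hand(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.5], index=list("abcd"))
        out = at.call_degs(p, fdr=0.05)
        assert np.allclose(out.q, [0.04, 0.04, 0.04, 0.5])
        assert out.is_deg.sum() == 3

    def test_all_ones_yield_no_degs(self):
        out = at.call_degs(pd.Series([1.0] * 5))
        assert out.is_deg.sum() == 0

    def test_q_dominates_p(self, rng):
        p = pd.Series(rng.uniform(size=200))
        out = at.call_degs(p)
        assert (out.q >= out.p - 1e-12).all()

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            at.call_degs(pd.Series(dtype=float))

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            at.call_degs(pd.Series([0.5, 1.5]))


def _curves(archetype, n_genes, ages, rng, noise=0.05):
    shapes = {
        "linear_up": 0.05 * (ages - ages.mean()),
        "linear_down": -0.05 * (ages - ages.mean()),
        "u_shape": 0.004 * (ages - 10.0) ** 2,
        "inverted_u": -0.004 * (ages - 10.0) ** 2,
    }
    base = shapes[archetype]
    return [base + rng.normal(0, noise, size=len(ages)) for _ in range(n_genes)]


class TestClustering:
    def test_antipodal_shapes_fully_separated(self, rng):
        ages = np.linspace(3, 35, 50)
        rows = _curves("linear_up", 20, ages, rng) + _curves("linear_down", 20, ages, rng)
        fitted = pd.DataFrame(rows, index=[f"g{i}" for i in range(40)])
        labels, _ = at.cluster_trajectories(fitted, k=2)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_duplicate_vectors_share_a_cluster(self, rng):
        ages = np.linspace(3, 35, 30)
        rows = _curves("linear_up", 5, ages, rng) + _curves("u_shape", 5, ages, rng)
        rows.append(rows[0].copy())  # exact duplicate of the first gene
        fitted = pd.DataFrame(rows, index=[f"g{i}" for i in range(11)])
        labels, _ = at.cluster_trajectories(fitted, k=2)
        assert labels.iloc[0] == labels.iloc[-1]

    def test_four_planted_archetypes_recovered(self, rng):
        ages = np.linspace(3, 35, 60)
        rows, truth = [], []
        for i, arch in enumerate(["linear_up", "linear_down", "u_shape", "inverted_u"]):
            rows += _curves(arch, 50, ages, rng, noise=0.1)
            truth += [i] * 50
        fitted = pd.DataFrame(rows, index=[f"g{i}" for i in range(200)])
        labels, _ = at.cluster_trajectories(fitted, k=4)
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_labels_run_from_one_to_k(self, rng):
        ages = np.linspace(3, 35, 30)
        rows = _curves("linear_up", 6, ages, rng) + _curves("linear_down", 6, ages, rng)
        fitted = pd.DataFrame(rows, index=[f"g{i}" for i in range(12)])
        labels, _ = at.cluster_trajectories(fitted, k=2)
        assert set(labels) == {1, 2}

    def test_too_few_genes_rejected(self, rng):
        fitted = pd.DataFrame(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError, match="k=4"):
            at.cluster_trajectories(fitted, k=4)


class TestSummarizeAndLoess:
    def test_single_gene_cluster(self, rng):
        ages = np.linspace(3, 35, 20)
        vec = 0.05 * ages + rng.normal(0, 0.1, size=20)
        summ = at.summarize_cluster(pd.DataFrame([vec], index=["g"]), ages)
        assert np.allclose(summ["mean"], vec)
        assert np.allclose(summ["sd"], 0.0)

    def test_loess_reproduces_a_line(self):
        x = np.linspace(0, 10, 40)
        y = 2.0 + 3.0 * x
        grid = np.linspace(0.5, 9.5, 91)
        fit = at.loess_smooth(x, y, grid, span=0.75, degree=2)
        assert np.abs(fit - (2.0 + 3.0 * grid)).max() < 1e-6

    def test_loess_reproduces_a_quadratic(self):
        x = np.linspace(0, 10, 40)
        y = 1.0 - 2.0 * x + 0.5 * x**2
        grid = np.linspace(0.5, 9.5, 50)
        fit = at.loess_smooth(x, y, grid, span=0.6, degree=2)
        assert np.abs(fit - (1.0 - 2.0 * grid + 0.5 * grid**2)).max() < 1e-6

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            at.summarize_cluster(pd.DataFrame(columns=range(5)), np.arange(5.0))


class TestInflection:
    def test_quadratic_vertex_recovered(self):
        grid = np.arange(3.0, 35.01, 0.1)
        curve = (grid - 10.0) ** 2
        est = at.estimate_inflection(grid, curve)
        assert est.extremum_age == pytest.approx(10.0, abs=1e-9)
        assert est.extremum_type == "minimum"
        assert est.is_interior

    def test_monotone_curve_hits_boundary(self):
        grid = np.arange(3.0, 35.01, 0.1)
        est = at.estimate_inflection(grid, 0.1 * grid)
        assert not est.is_interior
        assert est.extremum_age in (grid[0], grid[-1])

    def test_flat_curve_reported_as_non_interior_minimum(self):
        grid = np.arange(0.0, 10.01, 0.1)
        est = at.estimate_inflection(grid, np.zeros_like(grid))
        assert est.extremum_type == "minimum"
        assert est.extremum_age == grid[0]
        assert not est.is_interior

    def test_margin_controls_interiority(self):
        grid = np.arange(3.0, 35.01, 0.1)
        curve = (grid - 3.8) ** 2  # vertex just inside the range
        assert at.estimate_inflection(grid, curve, margin=0.5).is_interior
        assert not at.estimate_inflection(grid, curve, margin=1.0).is_interior

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            at.estimate_inflection(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestClassify:
    def test_ramp_up(self):
        grid = np.arange(3.0, 35.01, 0.1)
        curve = 0.05 * grid
        est = at.estimate_inflection(grid, curve)
        assert at.classify_trajectory(curve, est) == "linear_up"

    def test_planted_inverted_u(self):
        grid = np.arange(3.0, 35.01, 0.1)
        curve = -((grid - 10.0) ** 2)
        est = at.estimate_inflection(grid, curve)
        assert at.classify_trajectory(curve, est) == "nonlinear_inverted_u"

    def test_shift_invariance(self):
        grid = np.arange(3.0, 35.01, 0.1)
        for curve in ((grid - 10.0) ** 2, -0.05 * grid):
            est1 = at.estimate_inflection(grid, curve)
            est2 = at.estimate_inflection(grid, curve + 100.0)
            assert at.classify_trajectory(curve, est1) == at.classify_trajectory(
                curve + 100.0, est2
            )


class TestRunComparison:
    def test_identical_sets(self):
        out = at.compare_deg_sets({"a", "b"}, {"a", "b"})
        assert out["overlap"] == 1.0 and out["jaccard"] == 1.0

    def test_disjoint_sets(self):
        out = at.compare_deg_sets({"a"}, {"b"})
        assert out["overlap"] == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            at.compare_deg_sets(set(), {"a"})

    def test_self_correlation_is_one(self, rng):
        ages = np.linspace(3, 35, 30)
        fitted = pd.DataFrame(rng.normal(size=(10, 30)),
                              index=[f"g{i}" for i in range(10)])
        r = at.coefficient_correlation(fitted, fitted, ages, ages)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_no_shared_genes_rejected(self, rng):
        ages = np.linspace(3, 35, 10)
        a = pd.DataFrame(rng.normal(size=(3, 10)), index=["a", "b", "c"])
        b = pd.DataFrame(rng.normal(size=(3, 10)), index=["x", "y", "z"])
        with pytest.raises(ValueError, match="shared"):
            at.coefficient_correlation(a, b, ages, ages)

    def test_slope_summary_of_exact_ramp(self):
        ages = np.linspace(3.0, 35.0, 20)
        fitted = pd.DataFrame([2.0 * ages], index=["g"])
        assert slope_summary(fitted, ages)[0] == pytest.approx(2.0, abs=1e-12)


def test_reported_model_achieves_grid_minimum_aic(rng):
    """AIC minimality against an exhaustive per-order refit oracle."""
    grid = at.ArimaGrid()
    for i in range(8):
        y = rng.normal(size=60) + (0.04 * (i % 3)) * np.arange(60)
        best = at.fit_gene_arima(y, grid)
        refits = []
        for p, d, q in grid.orders():
            if (p, d, q) == (0, 0, 0):
                refits.append(null_fit(y))
            else:
                refits.append(fit_arma(y, (p, d, q), with_mean=d == 0))
        assert best.aic <= min(f.aic for f in refits) + 1e-9
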