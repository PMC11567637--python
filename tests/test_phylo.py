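"""Tree covariance, design standardization, VIF and ordinal-model tests."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from polyselect import synthetic
from polyselect.phylo import (
    fit_cumulative,
    fit_cumulative_phylo,
    marginal_r2,
    pool_draws,
    sample_trees,
    standardize_predictors,
    vcv_from_tree,
    vif,
)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestVcv:
    def test_star_tree_identity(self):
        t = _tree("(A:1,B:1,C:1,D:1);")
        t.is_rooted = True
        v = vcv_from_tree(t)
        assert np.allclose(v.C, np.eye(4))

    def test_two_sisters_path_sum(self):
        t = _tree("((A:0.2,B:0.2):0.8);")
        t.is_rooted = True
        v = vcv_from_tree(t, scale_to_unit_height=False)
        idx = {l: i for i, l in enumerate(v.labels)}
        expected = np.array([[1.0, 0.8], [0.8, 1.0]])
        perm = [idx["A"], idx["B"]]
        assert np.allclose(v.C[np.ix_(perm, perm)], expected)

    def test_ultrametric_constant_diagonal(self):
        t = synthetic.simulate_tree(30, seed=1)
        C = vcv_from_tree(t).C
        assert np.allclose(np.diag(C), 1.0, atol=1e-9)
        # diagonal dominates off-diagonal in every row
        off = C - np.diag(np.diag(C))
        assert np.all(np.diag(C)[:, None] >= off - 1e-12)

    def test_duplicate_tips_rejected(self):
        t = _tree("((A:1,B:1):1,C:2);")
        t.is_rooted = True
        for leaf in t.leaf_node_iter():
            if leaf.taxon.label == "C":
                leaf.taxon.label = "A"
        with pytest.raises(ValueError, match="duplicate"):
            vcv_from_tree(t)


class TestDesign:
    def _traits(self):
        return pd.DataFrame({
            "trophic": [1, 0, 0, 1, 0, 0],
            "migration": [0, 0, 1, 0, 1, 0],
            "territoriality": [1, 1, 0, 0, 1, 1],
            "seasonality": [0.5, 1.0, 2.0, 4.0, 8.0, 16.0],
        })

    def test_two_sd_scaling_and_centering(self):
        X, scaling = standardize_predictors(self._traits())
        assert X["seasonality"].std(ddof=1) == pytest.approx(0.5)
        for col in ("trophic", "migration", "territoriality"):
            assert X[col].mean() == pytest.approx(0.0, abs=1e-12)
        assert scaling["seasonality"]["log"] is True

    def test_hand_computed_design(self):
        X, _ = standardize_predictors(self._traits())
        ls = np.log(self._traits()["seasonality"].to_numpy())
        expected = (ls - ls.mean()) / (2 * ls.std(ddof=1))
        assert np.allclose(X["seasonality"], expected)
        assert np.allclose(X["trophic:seasonality"],
                           X["trophic"] * X["seasonality"])

    def test_zero_variance_column_named_in_error(self):
        bad = self._traits().assign(migration=0)
        with pytest.raises(ValueError, match="migration"):
            standardize_predictors(bad)

    def test_nonpositive_seasonality_rejected(self):
        bad = self._traits().assign(seasonality=[0.0, 1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="seasonality"):
            standardize_predictors(bad)


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]})
        assert np.allclose(vif(X), 1.0)

    def test_duplicated_column_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4],
                          "c": [0.0, 1, 0, 1]})
        assert np.isinf(vif(X)["a"])

    def test_correlated_toy_matrix_against_regression_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=100)
        b = a + rng.normal(scale=0.5, size=100)
        c = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": b, "c": c})
        got = vif(X)
        for col in X.columns:
            others = X.drop(columns=[col]).to_numpy()
            A = np.column_stack([np.ones(100), others])
            yj = X[col].to_numpy()
            coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
            r2 = 1 - ((yj - A @ coef) ** 2).sum() / ((yj - yj.mean()) ** 2).sum()
            assert got[col] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestOrdinalFits:
    def test_degenerate_response_rejected(self):
        X = np.linspace(0, 1, 20)[:, None]
        with pytest.raises(ValueError, match="degenerate"):
            fit_cumulative(np.zeros(20, dtype=int), X, chains=1, iterations=10)

    def test_constant_column_rejected(self):
        y = np.array([0, 1, 2, 3, 4] * 4)
        X = np.ones((20, 1))
        with pytest.raises(ValueError, match="constant column"):
            fit_cumulative(y, X, chains=1, iterations=10)

    def test_nonpsd_covariance_rejected(self):
        y = np.array([0, 1, 2, 3] * 5)
        X = np.linspace(-1, 1, 20)[:, None]
        C = -np.eye(20)
        with pytest.raises(ValueError, match="positive semi-definite"):
            fit_cumulative_phylo(y, X, C, chains=1, iterations=10)

    def test_zero_slope_data_ci_covers_zero(self):
        rng = np.random.default_rng(0)
        n = 200
        X = rng.normal(size=(n, 1))
        l = rng.standard_normal(n)  # no dependence on X
        y = synthetic.threshold_scores(l, synthetic.cutpoints_from_shares(
            (0.3, 0.25, 0.2, 0.15, 0.1)))
        f = fit_cumulative(y, X, chains=2, iterations=300, warmup=300, seed=1)
        b = f.flat()[:, 0]
        assert np.quantile(b, 0.025) <= 0 <= np.quantile(b, 0.975)

    def test_positive_latitude_effect_detected(self):
        """Monotone-in-latitude scores give posterior slope mass above zero."""
        rng = np.random.default_rng(1)
        n = 300
        lat = rng.uniform(0, 60, n)
        x = (lat - lat.mean()) / (2 * lat.std())
        l = 1.5 * x + rng.standard_normal(n)
        y = synthetic.threshold_scores(l, synthetic.cutpoints_from_shares(
            (0.4, 0.2, 0.15, 0.15, 0.1)))
        f = fit_cumulative(y, x[:, None], chains=2, iterations=300, warmup=300, seed=2)
        assert (f.flat()[:, 0] > 0).mean() > 0.95

    def test_cutpoint_ordering_in_every_draw(self):
        rng = np.random.default_rng(2)
        n = 150
        X = rng.normal(size=(n, 2))
        l = X @ [0.5, -0.5] + rng.standard_normal(n)
        y = synthetic.threshold_scores(l, synthetic.cutpoints_from_shares(
            (0.3, 0.25, 0.2, 0.15, 0.1)))
        f = fit_cumulative(y, X, chains=2, iterations=200, warmup=200, seed=3)
        taus = f.to_frame()[[c for c in f.param_names if c.startswith("tau:")]]
        assert (taus.diff(axis=1).iloc[:, 1:] > 0).all().all()

    def test_logit_link_runs_and_scales_up_cutpoints(self):
        rng = np.random.default_rng(3)
        n = 200
        X = rng.normal(size=(n, 1))
        l = 1.0 * X[:, 0] + rng.logistic(size=n)
        y = synthetic.threshold_scores(l, np.array([-1.0, 0.0, 1.0, 2.0]))
        f = fit_cumulative(y, X, link="logit", chains=2, iterations=250,
                           warmup=400, seed=4)
        b = f.flat()[:, 0].mean()
        assert 0.4 < b < 1.8

    def test_phylo_logit_not_supported(self):
        y = np.array([0, 1, 2, 3] * 5)
        X = np.linspace(-1, 1, 20)[:, None]
        with pytest.raises(NotImplementedError):
            fit_cumulative_phylo(y, X, np.eye(20), link="logit", chains=1,
                                 iterations=10)

    def test_phylo_identity_matches_plain_cumulative(self):
        """With C=identity and the variance fixed at 0 the phylogenetic model
        reduces to the plain cumulative probit."""
        rng = np.random.default_rng(4)
        n = 250
        X = rng.normal(size=(n, 1))
        l = 0.8 * X[:, 0] + rng.standard_normal(n)
        y = synthetic.threshold_scores(l, synthetic.cutpoints_from_shares(
            (0.3, 0.25, 0.2, 0.15, 0.1)))
        fp = fit_cumulative_phylo(y, X, np.eye(n), chains=2, iterations=400,
                                  warmup=400, seed=5, sigma2_fixed=0.0)
        fc = fit_cumulative(y, X, chains=2, iterations=400, warmup=400, seed=6)
        bp, bc = fp.flat()[:, 0], fc.flat()[:, 0]
        se = np.hypot(bp.std() / np.sqrt(len(bp) / 10), bc.std() / np.sqrt(len(bc) / 10))
        assert abs(bp.mean() - bc.mean()) < max(3 * se, 0.05)
        assert np.allclose(fp.flat()[:, -1], 0.0)


class TestPooling:
    def _fit(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        X = rng.normal(size=(n, 1))
        y = synthetic.threshold_scores(0.5 * X[:, 0] + rng.standard_normal(n),
                                       np.array([-1.0, 0.0, 1.0, 2.0]))
        return fit_cumulative(y, X, chains=1, iterations=100, warmup=100, seed=seed)

    def test_pooling_identical_fit_preserves_summary(self):
        f = self._fit(1)
        single = pool_draws([f]).summary()
        double = pool_draws([f, f]).summary()
        # mean and tail probability are exactly invariant; sd (ddof=1) and
        # interpolated quantiles shift at O(1/n) under duplication
        assert np.allclose(single["mean"], double["mean"], atol=0)
        assert np.allclose(single["p_two_sided"], double["p_two_sided"], atol=0)
        for col in ("sd", "ci66_lo", "ci66_hi", "ci95_lo", "ci95_hi"):
            assert np.allclose(single[col], double[col], atol=0.05)

    def test_pooled_draw_count(self):
        fits = [self._fit(s) for s in range(3)]
        pooled = pool_draws(fits)
        assert pooled.draws.shape[0] == sum(f.flat().shape[0] for f in fits)

    def test_pooling_order_invariant(self):
        fits = [self._fit(s) for s in range(3)]
        a = pool_draws(fits).summary()
        b = pool_draws(fits[::-1]).summary()
        assert np.allclose(a["mean"], b["mean"])
        assert np.allclose(a["ci95_lo"], b["ci95_lo"])

    def test_disjoint_supports_spanned(self):
        f1 = self._fit(1)
        f2 = self._fit(2)
        f2.draws = f2.draws + 100.0
        pooled = pool_draws([f1, f2])
        s = pooled.summary()
        assert (s["ci95_lo"] < 50).all() and (s["ci95_hi"] > 50).all()

    def test_mismatched_parameters_rejected(self):
        f1 = self._fit(1)
        f2 = self._fit(2)
        f2.param_names = list(f2.param_names)
        f2.param_names[0] = "beta:other"
        with pytest.raises(ValueError, match="differ"):
            pool_draws([f1, f2])

    def test_interval_nesting(self):
        s = pool_draws([self._fit(3)]).summary()
        assert (s["ci95_lo"] <= s["ci66_lo"]).all()
        assert (s["ci66_hi"] <= s["ci95_hi"]).all()


class TestMarginalR2:
    def test_zero_beta_gives_zero_r2(self):
        f = TestPooling()._fit(5)
        f.draws[:, :, 0] = 0.0
        X = np.random.default_rng(0).normal(size=(100, 1))
        out = marginal_r2(f, X)
        assert out["mean"] == pytest.approx(0.0, abs=1e-12)

    def test_r2_bounded_and_formula_limit(self):
        rng = np.random.default_rng(6)
        f = TestPooling()._fit(6)
        X = rng.normal(size=(100, 1))
        out = marginal_r2(f, X)
        assert np.all((out["draws"] >= 0) & (out["draws"] <= 1))
        # probit without a random effect: R2 = var(Xb)/(var(Xb)+1) per draw
        b = f.flat()[:, 0]
        vf = (X[:, 0] ** 2).mean() - X[:, 0].mean() ** 2
        expected = (b**2 * vf) / (b**2 * vf + 1.0)
        assert np.allclose(out["draws"], expected, atol=1e-12)


class TestSampleTrees:
    def test_deterministic_and_distinct(self):
        trees = [synthetic.simulate_tree(5, seed=s) for s in range(100)]
        a = sample_trees(trees, k=50, seed=1)
        b = sample_trees(trees, k=50, seed=1)
        assert [id(t) for t in a] == [id(t) for t in b]
        assert len({id(t) for t in a}) == 50

    def test_k_equal_to_size_returns_all(self):
        trees = [synthetic.simulate_tree(4, seed=s) for s in range(7)]
        out = sample_trees(trees, k=7, seed=2)
        assert {id(t) for t in out} == {id(t) for t in trees}

    def test_oversampling_with_replacement(self):
        trees = [synthetic.simulate_tree(4, seed=s) for s in range(3)]
        out = sample_trees(trees, k=10, seed=3)
        assert len(out) == 10
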