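import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

from phylossb.mk import binary_rate_matrix
from phylossb.phyloglm import collinearity_diagnostics, fit_phylo_logistic
from phylossb.simulate import simulate_mk, simulate_tree
from phylossb.trees import Phylogeny


def _star_tree(n):
    labels = [f"t{i}" for i in range(n)]
    return Phylogeny.from_newick("(" + ",".join(f"{l}:1" for l in labels) + ");"), labels


class TestStarTreeEquivalence:
    def test_matches_ordinary_logistic_across_designs(self):
        # with no shared history the phylogenetic model must collapse to
        # ordinary logistic regression
        tree, labels = _star_tree(80)
        rng = np.random.default_rng(10)
        for rep in range(20):
            x1 = rng.integers(0, 2, 80)
            x2 = rng.integers(0, 2, 80)
            y = (rng.random(80) < expit(-0.5 + x1 - 0.4 * x2)).astype(int)
            if y.min() == y.max() or len(set(x1)) < 2 or len(set(x2)) < 2:
                continue
            pred = pd.DataFrame({"x1": x1, "x2": x2}, index=labels)
            fit = fit_phylo_logistic(tree, dict(zip(labels, y)), pred,
                                     n_boot=0, seed=rep)
            ref = sm.Logit(y, np.column_stack([np.ones(80), x1, x2])).fit(disp=0)
            np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.params,
                                       atol=1e-4)


class TestFitBehaviour:
    def test_separation_flagged_when_response_equals_predictor(self):
        tree = simulate_tree(150, "yule", scale_root_age=100.0, seed=20)
        hist = simulate_mk(tree, binary_rate_matrix(0.02, 0.02), seed=1)
        soc = np.array([hist.node_states[i] for i in range(150)])
        pred = pd.DataFrame({"sociality": soc}, index=tree.tip_labels)
        fit = fit_phylo_logistic(tree, dict(zip(tree.tip_labels, soc)), pred,
                                 n_boot=0, seed=2)
        assert fit.separation

    def test_monomorphic_response_rejected(self):
        tree, labels = _star_tree(20)
        pred = pd.DataFrame({"x": np.arange(20) % 2}, index=labels)
        with pytest.raises(ValueError, match="monomorphic"):
            fit_phylo_logistic(tree, {l: 1 for l in labels}, pred)

    def test_disjoint_species_rejected(self):
        tree, _ = _star_tree(10)
        pred = pd.DataFrame({"x": [0, 1]}, index=["zz1", "zz2"])
        with pytest.raises(ValueError, match="overlap"):
            fit_phylo_logistic(tree, {"zz1": 0, "zz2": 1}, pred)

    def test_equal_weights_match_unweighted(self):
        tree, labels = _star_tree(60)
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 60)
        y = (rng.random(60) < expit(-0.3 + x)).astype(int)
        pred = pd.DataFrame({"x": x}, index=labels)
        resp = dict(zip(labels, y))
        f0 = fit_phylo_logistic(tree, resp, pred, n_boot=0, seed=4)
        f1 = fit_phylo_logistic(tree, resp, pred, n_boot=0, seed=4,
                                weights={l: 2.0 for l in labels})
        np.testing.assert_allclose(f0.coefficients, f1.coefficients, atol=1e-6)

    def test_bootstrap_ci_covers_estimate(self):
        tree = simulate_tree(120, "yule", scale_root_age=100.0, seed=21)
        hist = simulate_mk(tree, binary_rate_matrix(0.02, 0.02), seed=5)
        soc = np.array([hist.node_states[i] for i in range(120)])
        rng = np.random.default_rng(6)
        y = (rng.random(120) < expit(-1.0 + 1.2 * soc)).astype(int)
        pred = pd.DataFrame({"sociality": soc}, index=tree.tip_labels)
        fit = fit_phylo_logistic(tree, dict(zip(tree.tip_labels, y)), pred,
                                 n_boot=60, seed=7)
        assert fit.ci_lower["sociality"] <= fit.coefficients["sociality"] \
            <= fit.ci_upper["sociality"]
        assert 0 < fit.p_values["sociality"] <= 1


class TestCalibration:
    def test_type_one_error_of_bootstrap_test(self):
        # response evolves as Mk, independent of the predictor: the sociality
        # CI should exclude 0 in at most ~10% of replicates
        tree = simulate_tree(150, "yule", scale_root_age=100.0, seed=22)
        soc_hist = simulate_mk(tree, binary_rate_matrix(0.02, 0.02), seed=8)
        soc = np.array([soc_hist.node_states[i] for i in range(150)])
        pred = pd.DataFrame({"sociality": soc}, index=tree.tip_labels)
        rejections = 0
        n_rep = 60
        used = 0
        for s in range(n_rep):
            resp_hist = simulate_mk(tree, binary_rate_matrix(0.02, 0.02),
                                    seed=3000 + s)
            y = np.array([resp_hist.node_states[i] for i in range(150)])
            if y.min() == y.max():
                continue
            used += 1
            fit = fit_phylo_logistic(tree, dict(zip(tree.tip_labels, y)), pred,
                                     n_boot=60, seed=s)
            lo, hi = fit.ci_lower["sociality"], fit.ci_upper["sociality"]
            rejections += (lo > 0) or (hi < 0)
        assert used >= 40
        assert rejections <= 0.10 * used

    def test_noise_effort_covariate_barely_moves_estimate(self):
        tree = simulate_tree(200, "yule", scale_root_age=100.0, seed=23)
        soc_hist = simulate_mk(tree, binary_rate_matrix(0.02, 0.02), seed=9)
        soc = np.array([soc_hist.node_states[i] for i in range(200)])
        rng = np.random.default_rng(11)
        shifts = []
        for s in range(8):
            y = (rng.random(200) < expit(-1.5 + 1.2 * soc)).astype(int)
            if y.min() == y.max():
                continue
            effort = rng.standard_normal(200)
            p0 = pd.DataFrame({"sociality": soc}, index=tree.tip_labels)
            p1 = pd.DataFrame({"sociality": soc, "effort": effort},
                              index=tree.tip_labels)
            resp = dict(zip(tree.tip_labels, y))
            f0 = fit_phylo_logistic(tree, resp, p0, n_boot=0, seed=s)
            f1 = fit_phylo_logistic(tree, resp, p1, n_boot=0, seed=s)
            shifts.append(abs(f0.coefficients["sociality"]
                              - f1.coefficients["sociality"]))
        assert np.mean(shifts) < 0.2


class TestCollinearity:
    def test_independent_predictors_low_rho_and_vif(self, rng):
        x1 = rng.integers(0, 2, 1000)
        x2 = rng.integers(0, 2, 1000)
        diag = collinearity_diagnostics(pd.DataFrame({"x1": x1, "x2": x2}))
        assert abs(diag.spearman.iloc[0, 1]) < 0.1
        assert (diag.vif < 1.1).all()
        assert np.allclose(np.diag(diag.spearman), 1.0)

    def test_duplicated_predictor_capped(self, rng):
        x = rng.integers(0, 2, 100)
        diag = collinearity_diagnostics(pd.DataFrame({"a": x, "b": x}))
        assert diag.capped == ["a", "b"]
        assert (diag.vif >= 1e6 - 1).all()

    def test_single_predictor_vif_one(self, rng):
        x = rng.integers(0, 2, 50)
        diag = collinearity_diagnostics(pd.DataFrame({"a": x}))
        assert diag.vif["a"] == 1.0

    def test_constant_predictor_named_in_error(self, rng):
        df = pd.DataFrame({"a": rng.integers(0, 2, 50), "b": np.ones(50)})
        with pytest.raises(ValueError, match="'b'"):
            collinearity_diagnostics(df)
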