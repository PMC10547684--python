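import math

import numpy as np
import pytest

from phylossb.mk import (
    AncestralReconstruction,
    MkFit,
    NoVariationError,
    aic,
    binary_rate_matrix,
    fit_mk,
    make_rate_matrix,
    marginal_ancestral_states,
    mk_loglik,
    node_state_ztest,
)
from phylossb.simulate import simulate_mk, simulate_tree
from phylossb.trees import Phylogeny

from .oracles import enumeration_loglik, enumeration_marginals

FLAT2 = np.array([0.5, 0.5])


class TestLoglik:
    def test_two_tips_zero_rates(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        ll = mk_loglik(t, {"A": 0, "B": 0}, binary_rate_matrix(0, 0), FLAT2)
        assert ll == pytest.approx(math.log(0.5))

    def test_three_tip_enumeration_example(self, three_tip_tree):
        Q = binary_rate_matrix(0.5, 0.5)
        states = {"A": 1, "B": 0, "C": 0}
        got = mk_loglik(three_tip_tree, states, Q, FLAT2)
        want = enumeration_loglik(three_tip_tree, states, Q, FLAT2)
        assert got == pytest.approx(want, abs=1e-10)

    def test_all_ambiguous_gives_zero(self, three_tip_tree):
        assert mk_loglik(three_tip_tree, {}, binary_rate_matrix(0.5, 0.2), FLAT2) == 0.0

    def test_impossible_configuration_returns_neg_inf(self):
        t = Phylogeny.from_newick("(A:0,B:0);")
        ll = mk_loglik(t, {"A": 0, "B": 1}, binary_rate_matrix(0.4, 0.4), FLAT2)
        assert ll == -np.inf

    def test_state_outside_alphabet(self, three_tip_tree):
        with pytest.raises(ValueError, match="alphabet"):
            mk_loglik(three_tip_tree, {"A": 3, "B": 0, "C": 0},
                      binary_rate_matrix(0.1, 0.1), FLAT2)

    @pytest.mark.parametrize("newick", [
        "(A:1,B:2);",
        "((A:1,B:1):1,C:2);",
        "(A:1,B:1,C:1,D:1);",                      # star polytomy
        "(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);",
        "((A:0.5,B:0.5,C:0.5):1,(D:1,E:0.3):0.5);",
    ])
    @pytest.mark.parametrize("q01,q10", [(0.05, 0.05), (0.5, 0.2), (2.0, 0.7)])
    def test_matches_enumeration_on_small_trees(self, newick, q01, q10, rng):
        tree = Phylogeny.from_newick(newick)
        Q = binary_rate_matrix(q01, q10)
        states = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
        if len(set(states.values())) < 2:
            states[tree.tip_labels[0]] = 1 - states[tree.tip_labels[0]]
        got = mk_loglik(tree, states, Q, FLAT2)
        want = enumeration_loglik(tree, states, Q, FLAT2)
        assert got == pytest.approx(want, abs=1e-9)

    def test_four_state_matches_enumeration(self, three_tip_tree, rng):
        off = rng.uniform(0.05, 0.5, size=(4, 4))
        Q = make_rate_matrix(off)
        prior = np.full(4, 0.25)
        states = {"A": 2, "B": 0, "C": 3}
        got = mk_loglik(three_tip_tree, states, Q, prior)
        want = enumeration_loglik(three_tip_tree, states, Q, prior)
        assert got == pytest.approx(want, abs=1e-9)

    def test_invariant_under_child_order(self):
        a = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        b = Phylogeny.from_newick("(C:2,(B:1,A:1):1);")
        Q = binary_rate_matrix(0.3, 0.8)
        st = {"A": 1, "B": 0, "C": 1}
        assert mk_loglik(a, st, Q, FLAT2) == pytest.approx(
            mk_loglik(b, st, Q, FLAT2), abs=1e-12)

    def test_fast_binary_path_matches_general_path(self, yule200, rng):
        from phylossb.mk import _binary_loglik_fast

        hist = simulate_mk(yule200, binary_rate_matrix(0.02, 0.01), seed=8)
        tips = yule200.states_array(hist.tip_states(), 2)
        for q01, q10 in [(0.02, 0.01), (0.3, 0.05), (1e-6, 2.0)]:
            general = mk_loglik(yule200, tips, binary_rate_matrix(q01, q10), FLAT2)
            fast = _binary_loglik_fast(yule200, tips, q01, q10, FLAT2)
            assert fast == pytest.approx(general, rel=1e-9)


class TestFit:
    def test_ard_beats_er_by_nesting(self, yule300):
        hist = simulate_mk(yule300, binary_rate_matrix(0.05, 0.01), seed=5)
        states = hist.tip_states()
        er = fit_mk(yule300, states, "ER", seed=0)
        ard = fit_mk(yule300, states, "ARD", seed=0)
        assert ard.log_likelihood >= er.log_likelihood - 1e-6
        assert er.n_free_params == 1 and ard.n_free_params == 2

    def test_monomorphic_tips_error(self, three_tip_tree):
        with pytest.raises(NoVariationError, match="no variation"):
            fit_mk(three_tip_tree, {"A": 1, "B": 1, "C": 1}, "ARD")

    def test_aic_formula(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-942.0, 8) == pytest.approx(1900.0)

    def test_constrained_mask_counts_free_params(self, yule200):
        hist = simulate_mk(yule200, binary_rate_matrix(0.05, 0.05), seed=6)
        mask = np.array([[False, True], [True, False]])
        fit = fit_mk(yule200, hist.tip_states(), mask, seed=1, n_restarts=2)
        assert fit.n_free_params == 2


class TestMarginals:
    def test_zero_rates_all_state_zero(self, cherry_pair_tree):
        fit = MkFit(
            rate_matrix=binary_rate_matrix(0, 0), root_prior=FLAT2,
            log_likelihood=0.0, n_free_params=0, converged=True,
            model="fixed", n_restarts=0,
        )
        rec = marginal_ancestral_states(
            cherry_pair_tree, {l: 0 for l in cherry_pair_tree.tip_labels}, fit)
        np.testing.assert_allclose(rec.internal_probabilities()[:, 0], 1.0)

    def test_matches_bayes_enumeration(self, three_tip_tree):
        Q = binary_rate_matrix(0.5, 0.5)
        states = {"A": 1, "B": 0, "C": 0}
        rec = marginal_ancestral_states(three_tip_tree, states, Q=Q, root_prior=FLAT2)
        want = enumeration_marginals(three_tip_tree, states, Q, FLAT2)
        np.testing.assert_allclose(rec.probabilities[3:], want[3:], atol=1e-10)

    def test_matches_enumeration_on_five_tips(self, rng):
        tree = Phylogeny.from_newick(
            "(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        Q = binary_rate_matrix(0.4, 0.9)
        states = {"A": 1, "B": 0, "C": 1, "D": 0, "E": 0}
        rec = marginal_ancestral_states(tree, states, Q=Q, root_prior=FLAT2)
        want = enumeration_marginals(tree, states, Q, FLAT2)
        np.testing.assert_allclose(rec.probabilities[5:], want[5:], atol=1e-10)

    def test_mirror_symmetry(self, cherry_pair_tree):
        Q = binary_rate_matrix(0.3, 0.3)
        rec1 = marginal_ancestral_states(
            cherry_pair_tree, {"A": 1, "B": 1, "C": 0, "D": 0}, Q=Q, root_prior=FLAT2)
        rec2 = marginal_ancestral_states(
            cherry_pair_tree, {"A": 0, "B": 0, "C": 1, "D": 1}, Q=Q, root_prior=FLAT2)
        by1 = rec1.by_clade(state=1)
        by2 = rec2.by_clade(state=0)
        for key in by1:
            assert by1[key] == pytest.approx(by2[key], abs=1e-10)

    def test_rows_sum_to_one(self, yule50):
        hist = simulate_mk(yule50, binary_rate_matrix(0.02, 0.02), seed=12)
        fit = fit_mk(yule50, hist.tip_states(), "ARD", seed=0, n_restarts=2)
        rec = marginal_ancestral_states(yule50, hist.tip_states(), fit)
        np.testing.assert_allclose(rec.probabilities.sum(axis=1), 1.0, atol=1e-9)


class TestNodeZTest:
    def _recs(self, tree, probs_at_root):
        out = []
        for p in probs_at_root:
            probs = np.full((tree.n_nodes, 2), 0.5)
            probs[tree.root] = (1 - p, p)
            out.append(AncestralReconstruction(tree=tree, probabilities=probs))
        return out

    def test_all_half_gives_z_zero_p_half(self, cherry_pair_tree):
        recs = self._recs(cherry_pair_tree, [0.5] * 10)
        res = node_state_ztest(recs, frozenset("ABCD"))
        assert res.z == 0.0
        assert res.p_value == pytest.approx(0.5)
        assert res.verdict == "equivocal"

    def test_high_probability_called_present(self, cherry_pair_tree, rng):
        probs = np.clip(0.9 + 0.01 * rng.standard_normal(100), 0, 1)
        res = node_state_ztest(self._recs(cherry_pair_tree, probs), frozenset("ABCD"))
        assert res.verdict == "present"
        assert res.p_value < 0.05

    def test_single_tree_is_error(self, cherry_pair_tree):
        with pytest.raises(ValueError, match="2"):
            node_state_ztest(self._recs(cherry_pair_tree, [0.9]), frozenset("ABCD"))

    def test_unmatched_node_excluded(self, cherry_pair_tree, three_tip_tree):
        recs = self._recs(cherry_pair_tree, [0.9, 0.9, 0.9])
        probs = np.full((three_tip_tree.n_nodes, 2), 0.5)
        recs.append(AncestralReconstruction(tree=three_tip_tree, probabilities=probs))
        res = node_state_ztest(recs, frozenset("ABCD"))
        assert res.n_trees == 3
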