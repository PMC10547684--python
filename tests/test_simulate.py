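import numpy as np
import pytest
from scipy.stats import binom

from phylossb.mk import NoVariationError, binary_rate_matrix, fit_mk
from phylossb.simulate import (
    make_fixture_dataset,
    simulate_dependent_pair,
    simulate_mk,
    simulate_threshold_trait,
    simulate_tree,
)


class TestSimulateTree:
    def test_five_tips_binary_topology(self):
        t = simulate_tree(5, "yule", seed=1)
        assert t.n_tips == 5
        assert t.n_nodes - t.n_tips == 4  # binary: n-1 internal nodes

    def test_root_age_rescaling(self):
        t = simulate_tree(40, "yule", scale_root_age=100.0, seed=2)
        assert t.node_ages()[t.root] == pytest.approx(100.0, abs=1e-9)

    def test_deterministic_newick_under_seed(self):
        a = simulate_tree(30, "yule", scale_root_age=50.0, seed=3)
        b = simulate_tree(30, "yule", scale_root_age=50.0, seed=3)
        assert a.to_newick() == b.to_newick()

    def test_birth_death_tree_is_ultrametric(self):
        t = simulate_tree(40, "birth_death", birth_rate=1.0, death_rate=0.4,
                          scale_root_age=80.0, seed=4)
        assert t.n_tips == 40
        t.node_ages()

    def test_infeasible_parameters(self):
        with pytest.raises(ValueError):
            simulate_tree(10, "birth_death", birth_rate=0.5, death_rate=0.5)
        with pytest.raises(ValueError):
            simulate_tree(1, "yule")

    def test_no_zero_length_branches(self):
        t = simulate_tree(100, "yule", seed=5)
        assert t.blen[:-1].min() > 0


class TestSimulateMk:
    def test_near_zero_rates_keep_root_state(self, yule50):
        hist = simulate_mk(yule50, binary_rate_matrix(1e-12, 1e-12),
                           root_state_policy=1, seed=1)
        assert hist.n_events == 0
        assert all(v == 1 for v in hist.tip_states().values())

    def test_fast_symmetric_rates_reach_stationarity(self):
        tree = simulate_tree(1000, "yule", scale_root_age=10.0, seed=6)
        hist = simulate_mk(tree, binary_rate_matrix(5.0, 5.0), seed=2)
        freq = np.mean(list(hist.tip_states().values()))
        assert freq == pytest.approx(0.5, abs=0.1)

    def test_event_count_matches_poisson_moment(self):
        # symmetric rates: the total event count is Poisson(q * tree length)
        tree = simulate_tree(100, "yule", scale_root_age=50.0, seed=7)
        q = 0.01
        lam = q * tree.blen[:-1].sum()
        counts = [simulate_mk(tree, binary_rate_matrix(q, q), seed=s).n_events
                  for s in range(50)]
        sem = np.sqrt(lam / 50)
        assert abs(np.mean(counts) - lam) < 3 * sem

    def test_history_events_consistent_with_node_states(self, yule50):
        hist = simulate_mk(yule50, binary_rate_matrix(0.05, 0.05), seed=3)
        for i in range(yule50.n_nodes - 1):
            s = hist.node_states[yule50.parent[i]]
            for (t, a, b) in hist.events[i]:
                assert a == s
                s = b
            assert s == hist.node_states[i]


class TestThresholdTrait:
    def test_boundary_prevalences(self, yule300):
        assert simulate_threshold_trait(yule300, 0.0, seed=1).sum() == 0
        assert simulate_threshold_trait(yule300, 1.0, seed=1).sum() == 300

    def test_rank_rule_exact_count(self, yule300):
        v = simulate_threshold_trait(yule300, 0.5, seed=2)
        assert v.sum() == 150

    def test_out_of_range_prevalence(self, yule300):
        with pytest.raises(ValueError):
            simulate_threshold_trait(yule300, 1.5)


class TestDependentPair:
    def test_zero_rates_give_monomorphic_traits(self, yule50):
        rates = {n: 0.0 for n in (
            "x_gain_y0", "x_gain_y1", "x_loss_y0", "x_loss_y1",
            "y_gain_x0", "y_gain_x1", "y_loss_x0", "y_loss_x1")}
        x, y, hist = simulate_dependent_pair(yule50, rates, seed=1,
                                             root_state_policy=0)
        assert len(set(x.values())) == 1 and len(set(y.values())) == 1
        with pytest.raises(NoVariationError):
            fit_mk(yule50, x, "ARD")

    def test_marginals_consistent_with_joint_history(self, yule200):
        rates = dict(x_gain_y0=0.01, x_gain_y1=0.01, x_loss_y0=0.005,
                     x_loss_y1=0.005, y_gain_x0=0.01, y_gain_x1=0.01,
                     y_loss_x0=0.005, y_loss_x1=0.005)
        x, y, hist = simulate_dependent_pair(yule200, rates, seed=2)
        tips = hist.tip_states()
        for label in yule200.tip_labels:
            joint = tips[label]
            assert x[label] == joint // 2
            assert y[label] == joint % 2


class TestFixtureDataset:
    def test_ssb_count_within_binomial_ci(self):
        ds = make_fixture_dataset(n_species=2000, ssb_prevalence=0.04, seed=0)
        lo, hi = binom.ppf([0.005, 0.995], 2000, 0.04)
        assert lo <= ds.truth["n_ssb_positive"] <= hi

    def test_byte_identical_csv_under_seed(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        make_fixture_dataset(n_species=120, seed=9).table.to_csv(p1, index=False)
        make_fixture_dataset(n_species=120, seed=9).table.to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truth_bookkeeping_matches_table(self, fixture_dataset):
        df = fixture_dataset.table
        truth = fixture_dataset.truth
        ssb = (df.male_ssb.astype(bool) | df.female_ssb.astype(bool))
        assert truth["n_ssb_positive"] == int(ssb.sum())
        assert truth["n_male_ssb"] == int(df.male_ssb.sum())
        assert truth["n_captivity_only_ssb"] == int(
            (ssb & (df.observed_context == "captivity")).sum())
        assert truth["n_multi_year_site"] == int(df.studied_multi_year_site.sum())

    def test_species_match_tree_tips(self, fixture_dataset):
        assert list(fixture_dataset.table.species) == fixture_dataset.tree.tip_labels

    def test_histories_recorded_for_recovery(self, fixture_dataset):
        assert set(fixture_dataset.histories) == {
            "sociality", "adulticide_male", "adulticide_female"}
        h = fixture_dataset.histories["sociality"]
        tips = h.tip_states()
        df = fixture_dataset.table.set_index("species")
        assert all(df.loc[s, "sociality"] == v for s, v in tips.items())
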