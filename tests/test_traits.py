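import numpy as np
import pandas as pd
import pytest

from phylossb.simulate import make_fixture_dataset
from phylossb.traits import (
    TraitTable,
    TraitTableError,
    apply_subset,
    load_trait_table,
    summarize_prevalence,
)


def _csv(tmp_path, df, name="traits.csv"):
    p = tmp_path / name
    df.to_csv(p, index=False)
    return p


def _minimal_frame(species, **overrides):
    n = len(species)
    base = {
        "species": species,
        "male_ssb": [0] * n,
        "female_ssb": [0] * n,
        "observed_context": ["unknown"] * n,
        "sociality": [0] * n,
        "adulticide_male": [0] * n,
        "adulticide_female": [0] * n,
        "citations": [10] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestLoading:
    def test_three_valid_rows(self, tmp_path):
        df = _minimal_frame(["a_a", "b_b", "c_c"])
        table = load_trait_table(_csv(tmp_path, df))
        assert len(table) == 3

    def test_duplicate_species_names_error(self, tmp_path):
        df = _minimal_frame(["Canis lupus", "canis_lupus", "x_y"])
        with pytest.raises(TraitTableError, match="canis_lupus"):
            load_trait_table(_csv(tmp_path, df))

    def test_missing_required_column_is_config_error(self, tmp_path):
        df = _minimal_frame(["a", "b"]).drop(columns=["sociality"])
        with pytest.raises(TraitTableError, match="sociality"):
            load_trait_table(_csv(tmp_path, df))

    def test_dialect_maps_columns(self, tmp_path):
        df = _minimal_frame(["a", "b"]).rename(columns={"male_ssb": "SSB_M"})
        table = load_trait_table(_csv(tmp_path, df), dialect={"male_ssb": "SSB_M"})
        assert len(table) == 2

    def test_invalid_rows_rejected_with_reason(self, tmp_path):
        df = _minimal_frame(["a", "b", "c"], male_ssb=[0, 2, 1])
        table = load_trait_table(_csv(tmp_path, df))
        assert len(table) == 2
        assert table.rejected is not None
        assert "male_ssb" in table.rejected["reason"].iloc[0]

    def test_fixture_round_trip(self, tmp_path):
        ds = make_fixture_dataset(n_species=50, seed=1)
        p1 = tmp_path / "t1.csv"
        ds.table.to_csv(p1, index=False)
        table = load_trait_table(p1)
        assert len(table) == 50
        p2 = tmp_path / "t2.csv"
        table.to_csv(p2)
        t1 = pd.read_csv(p1)
        t2 = pd.read_csv(p2)
        pd.testing.assert_frame_equal(
            t1[sorted(t1.columns)], t2[sorted(t1.columns)], check_dtype=False
        )


class TestSubsets:
    def test_subset_ii_drops_captivity_only_ssb(self):
        # 100 SSB-positive species, 20 observed only in captivity
        df = _minimal_frame([f"s{i}" for i in range(100)])
        df["male_ssb"] = 1
        df["observed_context"] = ["captivity"] * 20 + ["wild"] * 80
        table = TraitTable(df)
        out = apply_subset(table, "II")
        assert out.n_ssb_positive() == 80
        assert len(out) == 80

    def test_captivity_negatives_are_kept(self):
        df = _minimal_frame(["a", "b", "c"], observed_context=["captivity"] * 3)
        out = apply_subset(TraitTable(df), "II")
        assert len(out) == 3  # no SSB: nothing to drop

    def test_empty_table_any_subset(self):
        table = TraitTable(_minimal_frame([]))
        for s in ("I", "II", "III", "IV"):
            assert len(apply_subset(table, s)) == 0

    def test_unknown_subset_id(self):
        with pytest.raises(ValueError, match="subset"):
            apply_subset(TraitTable(_minimal_frame(["a"])), "V")

    def test_subset_iv_direction_and_inversion(self):
        df = _minimal_frame(["a", "b", "c"], citations=[10, 2000, 500])
        table = TraitTable(df)
        assert apply_subset(table, "IV", 1000).species == ["b"]
        assert apply_subset(table, "IV", 1000,
                            invert_citation_filter=True).species == ["a", "c"]

    def test_subset_iv_requires_complete_citations(self):
        df = _minimal_frame(["a", "b"], citations=[10, np.nan])
        with pytest.raises(TraitTableError, match="citations"):
            apply_subset(TraitTable(df), "IV")

    def test_subsets_nested_on_fixture(self, fixture_dataset):
        table = fixture_dataset.trait_table()
        sI = apply_subset(table, "I")
        sII = apply_subset(table, "II")
        assert sI.n_ssb_positive() >= sII.n_ssb_positive()
        for s in ("III", "IV"):
            sub = apply_subset(table, s)
            assert set(sub.species) <= set(sI.species)

    def test_subset_application_is_idempotent(self, fixture_dataset):
        table = fixture_dataset.trait_table()
        for s in ("I", "II", "III", "IV"):
            once = apply_subset(table, s)
            twice = apply_subset(once, s)
            pd.testing.assert_frame_equal(once.data, twice.data)

    def test_subset_ii_count_matches_generator_truth(self):
        ds = make_fixture_dataset(n_species=400, ssb_prevalence=0.25, seed=2)
        table = ds.trait_table()
        out = apply_subset(table, "II")
        expected = ds.truth["n_ssb_positive"] - ds.truth["n_captivity_only_ssb"]
        assert out.n_ssb_positive() == expected


class TestNameNormalization:
    def test_case_and_underscores_collapse(self):
        from phylossb.traits import normalize_species_name

        assert normalize_species_name("Canis lupus") == \
            normalize_species_name("canis_lupus")

    def test_synonym_map_applied(self):
        from phylossb.traits import normalize_species_name

        syn = {"Felis catus": "Felis_silvestris"}
        assert normalize_species_name("felis_catus", syn) == "felis_silvestris"


class TestPrevalence:
    def test_counts_match_generator_truth(self):
        ds = make_fixture_dataset(n_species=500, ssb_prevalence=0.1, seed=3)
        summ = summarize_prevalence(ds.trait_table())
        assert summ.n_ssb == ds.truth["n_ssb_positive"]
        assert summ.n_male == ds.truth["n_male_ssb"]
        assert summ.n_female == ds.truth["n_female_ssb"]

    def test_empty_ssb_set_gives_zero_counts_and_nan_pct(self):
        summ = summarize_prevalence(TraitTable(_minimal_frame(["a", "b"])))
        assert summ.n_ssb == 0
        assert np.isnan(summ.pct(0))

    def test_row_order_invariance(self, fixture_dataset):
        table = fixture_dataset.trait_table()
        shuffled = TraitTable(
            table.data.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        a, b = summarize_prevalence(table), summarize_prevalence(shuffled)
        assert (a.n_ssb, a.n_male, a.n_female, a.by_display, a.by_context) == \
               (b.n_ssb, b.n_male, b.n_female, b.by_display, b.by_context)

    def test_completeness_report_flags_missing(self):
        df = _minimal_frame(["a", "b"])
        df.loc[0, "sociality"] = np.nan
        rep = TraitTable(df).completeness_report()
        assert rep["sociality"] == pytest.approx(0.5)
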