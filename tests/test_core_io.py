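"""Designs, domain types, filtering and TSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nwdose import (
    AnalysisConfig,
    CountMatrix,
    InvalidDesignError,
    ParseError,
    build_field_design,
    build_lab_design,
    filter_low_counts,
    read_counts,
    read_design,
    read_phenotypes,
    write_counts,
    write_design,
    write_phenotypes,
)
from nwdose.core_io import TERM_COLUMNS, TERMS

from conftest import make_counts


class TestLabDesign:
    def test_default_triplicate_has_48_samples(self, lab_design):
        assert lab_design.n_samples == 48
        pairs = set(zip(lab_design.frame["n_level"], lab_design.frame["w_level"]))
        assert len(pairs) == 16

    def test_n_level_is_concentration_times_feed_volume(self, lab_design):
        # 0.625 mM over the 130 mL feed -> 0.08125 mmol of N supplied
        assert np.isclose(lab_design.frame["n_level"].min(), 0.08125)

    def test_single_replicate_gives_each_condition_once(self):
        design = build_lab_design(replicates=1)
        assert design.n_samples == 16
        assert design.frame.groupby(["n_level", "w_level"]).size().eq(1).all()

    def test_factorial_completeness(self):
        design = build_lab_design(replicates=3)
        cells = design.frame.groupby(["n_level", "w_level"]).size()
        assert (cells == 3).all() and len(cells) == 16

    def test_n_over_w_is_deterministic_ratio(self, lab_design):
        frame = lab_design.frame
        assert np.allclose(frame["n_over_w"], frame["n_level"] / frame["w_level"])

    @pytest.mark.parametrize("bad", [
        dict(n_conc_mM=[0.625, 1.25, 2.5]),          # wrong count
        dict(n_conc_mM=[0.625, 1.25, 2.5, 2.5]),      # duplicate
        dict(w_volumes_mL=[16.25, 32.5, 65.0, -1.0]),  # non-positive
        dict(replicates=0),
    ])
    def test_invalid_designs_rejected(self, bad):
        with pytest.raises(InvalidDesignError):
            build_lab_design(**bad)


class TestFieldDesign:
    def test_nineteen_cultivars_triplicate_gives_228(self):
        design = build_field_design([f"cv{i}" for i in range(19)], replicates=3)
        assert design.n_samples == 228
        assert design.is_field

    def test_single_cultivar_single_replicate_is_2x2(self):
        design = build_field_design(["IR64"], replicates=1)
        assert design.n_samples == 4
        assert set(design.frame["n_level"]) == {0.0, 150.0}
        assert set(design.frame["w_level"]) == {0.0, 1.0}

    def test_duplicate_cultivars_rejected(self):
        with pytest.raises(InvalidDesignError):
            build_field_design(["IR64", "IR64"])

    def test_empty_cultivar_list_rejected(self):
        with pytest.raises(InvalidDesignError):
            build_field_design([])

    def test_factorial_completeness_per_cultivar(self):
        design = build_field_design(["a", "b", "c"], replicates=2)
        cells = design.frame.groupby(["cultivar", "n_level", "w_level"]).size()
        assert (cells == 2).all() and len(cells) == 12


class TestStandardization:
    @pytest.mark.parametrize("design_fn", [
        build_lab_design,
        lambda: build_field_design(["a", "b", "c"], replicates=2),
    ])
    def test_columns_have_zero_mean_unit_variance(self, design_fn):
        frame = design_fn().frame
        for col in TERM_COLUMNS.values():
            assert abs(frame[col].mean()) < 1e-9
            assert abs(frame[col].var(ddof=0) - 1.0) < 1e-9

    def test_standardization_idempotent(self, lab_design):
        once = lab_design.restandardized()
        twice = once.restandardized()
        for col in TERM_COLUMNS.values():
            assert np.allclose(once.frame[col], twice.frame[col], atol=1e-12)
            assert np.allclose(once.frame[col], lab_design.frame[col], atol=1e-12)

    def test_interaction_not_collinear_with_main_effects(self, lab_design):
        pred = lab_design.predictors().to_numpy()
        corr = np.corrcoef(pred.T)
        assert abs(corr[0, 3]) < 0.2 and abs(corr[1, 3]) < 0.2


class TestCountMatrix:
    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_counts([[1, 2], [3, 4]], gene_ids=["g", "g"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_counts([[1, -2]])

    def test_design_mismatch_reported(self, lab_design):
        counts = make_counts(np.ones((3, 4), dtype=int))
        with pytest.raises(ValueError, match="do not match"):
            counts.check_matches_design(lab_design)


class TestFilterLowCounts:
    def test_total_127_removed_128_kept(self, config):
        values = np.zeros((2, 48), dtype=int)
        values[0, :127] = 1  # total 127: below threshold
        values[1, :] = 100   # comfortably above, median 100
        kept = filter_low_counts(make_counts(values), config)
        assert kept.gene_ids == ["g1"]

    def test_all_zero_gene_removed(self, config):
        values = np.vstack([np.zeros(10, dtype=int), np.full(10, 50)])
        kept = filter_low_counts(make_counts(values), config)
        assert kept.gene_ids == ["g1"]

    def test_zero_median_gene_removed_despite_high_total(self, config):
        # huge total concentrated in few samples, median 0
        values = np.zeros((1, 10), dtype=int)
        values[0, :3] = 1000
        kept = filter_low_counts(make_counts(values), config)
        assert kept.gene_ids == []

    def test_passing_gene_retained_in_order(self, config):
        values = np.vstack([np.full(48, 50), np.full(48, 4)])  # totals 2400, 192
        kept = filter_low_counts(make_counts(values), config)
        assert kept.gene_ids == ["g0", "g1"]

    def test_empty_result_warns_not_raises(self, config):
        with pytest.warns(UserWarning, match="no genes"):
            out = filter_low_counts(make_counts(np.ones((2, 4), dtype=int)), config)
        assert out.shape[0] == 0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=1, max_value=400),
           st.integers(min_value=1, max_value=400),
           st.integers(min_value=0, max_value=2 ** 31))
    def test_filter_monotone_in_total_threshold(self, lo, hi, seed):
        lo, hi = sorted((lo, hi))
        rng = np.random.default_rng(seed)
        counts = make_counts(rng.integers(0, 30, size=(15, 8)))
        loose = filter_low_counts(counts, AnalysisConfig(min_total_count=lo))
        strict = filter_low_counts(counts, AnalysisConfig(min_total_count=hi))
        assert set(strict.gene_ids) <= set(loose.gene_ids)


class TestTsvRoundTrips:
    def test_counts_round_trip(self, tmp_path, rng):
        counts = make_counts(rng.integers(0, 100, size=(5, 4)))
        path = tmp_path / "counts.tsv"
        write_counts(counts, path)
        back = read_counts(path)
        pd.testing.assert_frame_equal(back.counts, counts.counts,
                                      check_names=False)

    def test_non_integer_count_names_offender(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\ts1\ts2\ng0\t1\t2\ng1\t3.7\t4\n")
        with pytest.raises(ParseError, match=r"3\.7.*g1.*line 3"):
            read_counts(path)

    def test_design_round_trip(self, tmp_path, lab_design):
        path = tmp_path / "design.tsv"
        write_design(lab_design, path)
        back = read_design(path)
        pd.testing.assert_frame_equal(back.frame, lab_design.frame)

    def test_phenotype_round_trip(self, tmp_path):
        from nwdose import PhenotypeTable
        table = PhenotypeTable(pd.DataFrame(
            {"shoot_biomass": [1.5, 2.5], "n_content": [2.0, 3.0]},
            index=pd.Index(["s1", "s2"], name="sample_id")))
        path = tmp_path / "ph.tsv"
        write_phenotypes(table, path)
        back = read_phenotypes(path)
        pd.testing.assert_frame_equal(back.data, table.data)

    def test_phenotype_samples_must_be_in_design(self, lab_design):
        from nwdose import PhenotypeTable
        table = PhenotypeTable(pd.DataFrame(
            {"shoot_biomass": [1.0]}, index=pd.Index(["nope"], name="sample_id")))
        with pytest.raises(ValueError, match="absent from design"):
            table.check_matches_design(lab_design)


class TestAnalysisConfig:
    def test_defaults_match_documented_thresholds(self, config):
        assert config.model_alpha == 0.005
        assert config.assoc_alpha == 0.05
        assert config.min_total_count == 128
        assert (config.spline_df, config.spline_knots) == (5, 3)
        assert config.fc_threshold == 1.25
        assert config.n_perm == 10_000

    @pytest.mark.parametrize("kwargs", [
        dict(model_alpha=0.0), dict(assoc_alpha=1.5),
        dict(min_total_count=0), dict(fc_threshold=0.9), dict(n_perm=-5),
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnalysisConfig(**kwargs)

    def test_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("model_alpha: 0.01\nn_perm: 500\n")
        cfg = AnalysisConfig.from_yaml(path)
        assert cfg.model_alpha == 0.01 and cfg.n_perm == 500

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            AnalysisConfig.from_mapping({"nope": 1})
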