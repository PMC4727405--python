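"""Per-gene cohort statistics: frequencies, binning, outliers, CNV, restriction."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cascadeviz import (
    CNVConfig,
    CNVTable,
    DataType,
    ExpressionMatrix,
    FlagTable,
    GeneList,
    OutlierConfig,
    ThresholdConfig,
    ValidationError,
    apply_gene_list_restriction,
    bin_frequency,
    cnv_summary,
    event_frequency,
    expression_summary,
    gene_detail,
    summarize_cohort,
)
from conftest import frame


def flag_table(values, samples=None, dt=DataType.MUTATION):
    samples = samples or [f"S{i}" for i in range(len(values))]
    return FlagTable(dt, frame({"G": values}, samples))


def oracle_bin(f, low_max, high_min):
    """Independent three-way comparison."""
    if f <= low_max:
        return "low"
    if f >= high_min:
        return "high"
    return "intermediate"


class TestEventFrequency:
    @pytest.mark.parametrize("values,expected", [
        ([0] * 10, (0.0, 0, 10)),
        ([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], (0.3, 3, 10)),
        ([1, 0, np.nan, np.nan], (0.5, 1, 2)),  # denominator excludes missing
    ])
    def test_hand_counted(self, values, expected):
        assert event_frequency(flag_table(values), "G") == expected

    def test_all_missing_has_no_frequency(self):
        assert event_frequency(flag_table([np.nan, np.nan]), "G") == (None, 0, 0)

    def test_unknown_gene(self):
        with pytest.raises(ValidationError, match="'NOPE'"):
            event_frequency(flag_table([1, 0]), "NOPE")

    @given(st.lists(st.sampled_from([0.0, 1.0, np.nan]), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bounds_invariant(self, values):
        f, n_ev, n_as = event_frequency(flag_table(values), "G")
        assert n_ev <= n_as <= len(values)
        if f is not None:
            assert 0.0 <= f <= 1.0

    def test_adding_flagged_sample_never_decreases_frequency(self):
        values = [1.0, 0.0, 0.0, np.nan]
        f0, _, _ = event_frequency(flag_table(values), "G")
        f1, _, _ = event_frequency(flag_table(values + [1.0]), "G")
        assert f1 >= f0


class TestBinFrequency:
    def test_extremes(self):
        cfg = ThresholdConfig(0.1, 0.3)
        assert bin_frequency(0.0, cfg) == "low"
        assert bin_frequency(1.0, cfg) == "high"
        assert bin_frequency(0.2, cfg) == "intermediate"

    def test_boundaries_closed_on_outer_bins(self):
        cfg = ThresholdConfig(0.1, 0.3)
        assert bin_frequency(0.1, cfg) == "low"
        assert bin_frequency(0.3, cfg) == "high"

    def test_grid_matches_comparison_oracle(self):
        cfg = ThresholdConfig(0.1, 0.3)
        for i in range(101):
            f = i / 100
            assert bin_frequency(f, cfg) == oracle_bin(f, 0.1, 0.3)

    @pytest.mark.parametrize("bad", [-0.01, 1.01, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            bin_frequency(bad, ThresholdConfig())

    def test_per_type_override(self):
        cfg = ThresholdConfig(0.1, 0.3, per_type={DataType.SPLICING: (0.01, 0.5)})
        assert bin_frequency(0.05, cfg, DataType.SPLICING) == "intermediate"
        assert bin_frequency(0.05, cfg, DataType.MUTATION) == "low"

    @given(st.floats(0, 0.98), st.floats(0.001, 1))
    @settings(max_examples=100, deadline=None)
    def test_raising_low_max_never_promotes(self, low, delta):
        """Raising low_max can only move genes toward the low bin, never away."""
        hi = 0.99
        low = min(low, hi - 1e-6)
        low2 = min(low + delta, hi - 1e-6)
        order = {"low": 0, "intermediate": 1, "high": 2}
        for i in range(0, 21):
            f = i / 20
            before = bin_frequency(f, ThresholdConfig(low, hi))
            after = bin_frequency(f, ThresholdConfig(low2, hi))
            assert order[after] <= order[before]


class TestExpressionSummary:
    def test_constant_vector_has_no_outliers(self):
        expr = ExpressionMatrix(frame({"G": [5, 5, 5, 5]}, list("abcd")))
        s = expression_summary(expr, "G", OutlierConfig())
        assert s.summary == 5.0 and not s.outlier_samples and not s.is_outlier_gene

    def test_single_extreme_sample_is_outlier(self):
        values = [1.0, 1.0, 1.0, 1.0, 100.0]
        expr = ExpressionMatrix(frame({"G": values}, list("abcde")))
        s = expression_summary(expr, "G", OutlierConfig(k_sd=1.0, min_outlier_fraction=0.2))
        # oracle: direct mean/sd computation
        mean = statistics.mean(values)
        sd = statistics.stdev(values)
        expected = {n for n, v in zip("abcde", values) if abs(v - mean) > sd}
        assert set(s.outlier_samples) == expected == {"e"}
        assert s.is_outlier_gene

    def test_median_mode(self):
        expr = ExpressionMatrix(frame({"G": [1, 2, 100]}, list("abc")))
        s = expression_summary(expr, "G", OutlierConfig(summary_stat="median"))
        assert s.summary == 2.0

    def test_single_value_skips_outlier_assessment(self):
        expr = ExpressionMatrix(frame({"G": [7.0, np.nan]}, list("ab")))
        s = expression_summary(expr, "G", OutlierConfig())
        assert s.summary == 7.0 and s.n_assessed == 1 and not s.is_outlier_gene

    def test_outlier_set_stable_under_mean_valued_padding(self):
        """Appending samples at the gene mean keeps the same samples outlying
        (asserted via oracle recomputation with the new sd, not naively)."""
        base = [1.0, 2.0, 3.0, 50.0]
        names = ["a", "b", "c", "d"]
        cfg = OutlierConfig(k_sd=2.0, min_outlier_fraction=0.01)
        mean = statistics.mean(base)
        padded = base + [mean] * 4
        pnames = names + [f"p{i}" for i in range(4)]
        s = expression_summary(ExpressionMatrix(frame({"G": padded}, pnames)), "G", cfg)
        sd = statistics.stdev(padded)
        expected = {n for n, v in zip(pnames, padded) if abs(v - mean) > cfg.k_sd * sd}
        assert set(s.outlier_samples) == expected


class TestCNVSummary:
    @pytest.mark.parametrize("values,dev,direction", [
        ([2, 2, 2, 2], 0.0, "neutral"),
        ([2, 2, 4, 4], 1.0, "gain"),
        ([1, 1, 2, 2], -0.5, "loss"),
    ])
    def test_arithmetic(self, values, dev, direction):
        t = CNVTable(frame({"G": values}, list("abcd")))
        s = cnv_summary(t, "G", CNVConfig())
        assert s.mean_deviation == pytest.approx(dev)
        assert s.direction == direction

    def test_all_missing_yields_absent(self):
        t = CNVTable(frame({"G": [np.nan, np.nan]}, list("ab")))
        assert cnv_summary(t, "G", CNVConfig()) is None

    def test_missing_excluded_from_denominator(self):
        t = CNVTable(frame({"G": [4.0, np.nan]}, list("ab")))
        s = cnv_summary(t, "G", CNVConfig())
        assert s.mean_deviation == pytest.approx(2.0)  # mean over 1 sample, not 2

    @given(st.lists(st.floats(0, 8), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_direction_is_sign_and_mode_invariant(self, values):
        t = CNVTable(frame({"G": values}, [f"s{i}" for i in range(len(values))]))
        rel = cnv_summary(t, "G", CNVConfig(mode="relative"))
        boo = cnv_summary(t, "G", CNVConfig(mode="boolean"))
        sign = (rel.mean_deviation > 0) - (rel.mean_deviation < 0)
        assert rel.direction == {1: "gain", -1: "loss", 0: "neutral"}[sign]
        assert rel.direction == boo.direction
        assert rel.mean_deviation == boo.mean_deviation

    def test_boolean_flag_uses_epsilon(self):
        t = CNVTable(frame({"G": [2.4, 2.4]}, list("ab")))
        assert not cnv_summary(t, "G", CNVConfig(epsilon=0.5)).boolean_flag
        assert cnv_summary(t, "G", CNVConfig(epsilon=0.3)).boolean_flag


class TestRestrictionAndCohort:
    def test_no_list_is_identity(self, small_dataset, chain_pathway):
        summaries = summarize_cohort(small_dataset, chain_pathway)
        assert apply_gene_list_restriction(summaries, None) is summaries

    def test_restriction_preserves_numbers(self, small_dataset, chain_pathway):
        summaries = summarize_cohort(small_dataset, chain_pathway,
                                     gene_list=GeneList("keep", {"A"}))
        assert not summaries["A"].restricted_out
        assert summaries["B"].restricted_out
        # numeric fields intact for detail views
        assert summaries["B"].frequencies[DataType.MUTATION].frequency == 1.0

    def test_family_nodes_get_no_summary(self, small_dataset, jak_pathway):
        summaries = summarize_cohort(small_dataset, jak_pathway)
        assert "JAK" not in summaries
        assert set(summaries) == {"RTK", "JAK1", "JAK2", "JAK3", "TYK2"}

    def test_gene_absent_everywhere_has_all_fields_absent(self, small_dataset, jak_pathway):
        s = summarize_cohort(small_dataset, jak_pathway)["JAK1"]
        assert not s.frequencies and s.expression is None and s.cnv is None

    def test_partial_data_only_fills_available_types(self, small_dataset, chain_pathway):
        small_dataset.expression = None
        small_dataset.cnv = None
        summaries = summarize_cohort(small_dataset, chain_pathway)
        s = summaries["A"]
        assert DataType.MUTATION in s.frequencies
        assert s.expression is None and s.cnv is None


class TestGeneDetail:
    def test_columns_follow_available_tables(self, small_dataset):
        d = gene_detail(small_dataset, "A")
        assert {"expression", "mutation", "splicing", "cnv", "cnv_deviation"} <= set(d.columns)
        assert list(d.index) == small_dataset.samples

    def test_sort_by_cnv_matches_sorting_oracle(self, small_dataset):
        d = gene_detail(small_dataset, "A", sort_by="cnv_deviation", ascending=False)
        assert list(d["cnv_deviation"]) == sorted(d["cnv_deviation"], reverse=True)

    def test_join_loses_no_records(self, small_dataset):
        """Cross-table join on sample id: every (gene, sample, type) value
        present in a source table is retrievable from the detail view."""
        for gene in ("A", "B", "C"):
            d = gene_detail(small_dataset, gene)
            for dt, ft in small_dataset.flag_tables.items():
                for s in ft.samples:
                    src = ft.flags.loc[gene, s]
                    got = d.loc[s, str(dt)]
                    assert (math.isnan(src) and math.isnan(got)) or src == got

    def test_unknown_gene_warns_and_returns_empty(self, small_dataset):
        with pytest.warns(UserWarning, match="ZZZ"):
            d = gene_detail(small_dataset, "ZZZ")
        assert d.empty and list(d.index) == small_dataset.samples
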