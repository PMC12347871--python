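"""Contingency statistics, multiple-testing adjustment, frequencies,
cluster detection and region summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from cnaforest import (
    GeneAnnotation,
    GenomicInterval,
    ValidationError,
    adjust_pvalues,
    annotate_cluster_frequencies,
    association_table,
    contingency,
    detect_clusters,
    fisher_exact,
    frequency_table,
    odds_ratio,
    region_frequency,
    region_summary,
)

from .conftest import make_segment, single_feature_matrix


def fisher_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p: enumerate all tables with the
    observed margins and sum hypergeometric point probabilities that do
    not exceed the observed table's (with a relative tolerance for float
    ties, the standard point-probability convention)."""
    n = a + b + c + d
    if n == 0:
        return 1.0  # empty table: single outcome with probability one
    r1, c1 = a + b, a + c
    support = range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = {k: hypergeom.pmf(k, n, c1, r1) for k in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestContingency:
    def test_planted_19q13_counts(self):
        matrix, labels = single_feature_matrix(17, 13, 18, 3)
        assert contingency(matrix, labels, "PSG1:cnLOH") == (13, 4, 3, 15)

    def test_all_zero_and_all_one_features(self):
        matrix, labels = single_feature_matrix(17, 0, 18, 0)
        assert contingency(matrix, labels, "PSG1:cnLOH") == (0, 17, 0, 18)
        matrix, labels = single_feature_matrix(17, 17, 18, 18)
        assert contingency(matrix, labels, "PSG1:cnLOH") == (17, 0, 18, 0)

    def test_unknown_feature_rejected(self):
        matrix, labels = single_feature_matrix(5, 2, 5, 1)
        with pytest.raises(ValidationError, match="GHOST"):
            contingency(matrix, labels, "GHOST:loss")


class TestFisherExact:
    def test_19q13_row_matches_enumeration_oracle(self):
        assert fisher_exact(13, 4, 3, 15) == pytest.approx(
            fisher_oracle(13, 4, 3, 15), rel=1e-9)

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact(0, 17, 0, 18) == 1.0

    def test_perfect_split_matches_oracle(self):
        assert fisher_exact(10, 0, 0, 10) == pytest.approx(
            fisher_oracle(10, 0, 0, 10), rel=1e-9)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact(-1, 2, 3, 4)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_agrees_with_oracle_on_small_tables(self, a, b, c, d):
        assert fisher_exact(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-7)


class TestOddsRatio:
    def test_19q13_value(self):
        assert odds_ratio(13, 4, 3, 15) == pytest.approx((13 * 15) / (4 * 3))
        assert odds_ratio(13, 4, 3, 15) == pytest.approx(16.25)

    def test_7p_value(self):
        assert odds_ratio(6, 11, 1, 17) == pytest.approx((6 * 17) / (11 * 1))

    def test_haldane_anscombe_on_zero_cell(self):
        assert odds_ratio(0, 17, 3, 15) == pytest.approx(
            (0.5 * 15.5) / (17.5 * 3.5))
        assert np.isfinite(odds_ratio(5, 0, 0, 5))

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30),
           st.integers(1, 30))
    def test_reciprocal_identity(self, a, b, c, d):
        assert odds_ratio(a, b, c, d) * odds_ratio(b, a, d, c) == (
            pytest.approx(1.0))


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_all_ones(self):
        assert adjust_pvalues([0.2]) == pytest.approx([0.2])
        np.testing.assert_allclose(adjust_pvalues([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.5, 1.5])

    def test_bonferroni_and_holm(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04], method="bonferroni"), [0.02, 0.08])
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.04], method="holm"), [0.02, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_bh_bounds_and_order_preservation(self, ps):
        qs = adjust_pvalues(ps)
        assert np.all(qs >= np.asarray(ps)) and np.all(qs <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(qs[order]) >= -1e-12)

    def test_null_type_one_error_control(self):
        # Fisher p over random null 2x2 tables at the cohort scale:
        # fraction below 0.05 stays at or below the nominal level
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(2000):
            a = rng.binomial(17, 0.3)
            c = rng.binomial(18, 0.3)
            ps.append(fisher_exact(a, 17 - a, c, 18 - c))
        assert np.mean(np.asarray(ps) <= 0.05) <= 0.05 + 0.02


class TestFrequencies:
    def test_per_group_fractions_with_reference(self):
        matrix, labels = single_feature_matrix(17, 13, 18, 3)
        ref, _ = single_feature_matrix(50, 24, 55, 25)
        table = frequency_table(matrix, labels, ref)
        row = table.loc["PSG1:cnLOH"]
        assert row.freq_mrd_pos == pytest.approx(13 / 17)
        assert row.freq_mrd_neg == pytest.approx(3 / 18)
        assert row.freq_reference == pytest.approx(49 / 105)

    def test_feature_absent_from_reference_counts_zero(self):
        matrix, labels = single_feature_matrix(5, 3, 5, 1)
        ref = single_feature_matrix(5, 2, 5, 2, feature_id="OTHER:loss")[0]
        table = frequency_table(matrix, labels, ref)
        assert table.loc["PSG1:cnLOH"].freq_reference == 0.0

    def test_single_sample_group_carrier(self):
        matrix, labels = single_feature_matrix(1, 1, 3, 0)
        assert frequency_table(matrix, labels).loc[
            "PSG1:cnLOH"].freq_mrd_pos == 1.0

    def test_empty_group_rejected(self):
        matrix, _ = single_feature_matrix(4, 2, 4, 1)
        with pytest.raises(ValidationError):
            frequency_table(matrix, np.ones(8, bool))

    def test_region_frequency_is_mean_over_member_genes(self):
        values = np.array([[1, 1], [1, 0], [0, 0], [0, 0]], dtype=np.uint8)
        matrix = __import__("cnaforest").GeneEventMatrix.from_arrays(
            ["S1", "S2", "S3", "S4"], ["A:cnLOH", "B:cnLOH"], values)
        labels = np.array([True, True, False, False])
        freqs = region_frequency(["A:cnLOH", "B:cnLOH"], matrix, labels)
        assert freqs["freq_mrd_pos"] == pytest.approx((1.0 + 0.5) / 2)
        assert freqs["freq_mrd_neg"] == 0.0


def catalog_chain(chrom, band, n, start=1_000_000, gap=100_000,
                  width=50_000, prefix="G"):
    genes = []
    pos = start
    for i in range(n):
        genes.append(GeneAnnotation(f"{prefix}{i}",
                                    GenomicInterval(chrom, pos,
                                                    pos + width - 1), band))
        pos += width + gap
    return genes


class TestDetectClusters:
    def test_no_shared_event_no_cluster(self, tiny_catalog):
        # no two neighboring top features share an event type
        ids = ["A0:loss", "A1:gain", "A2:cnLOH"]
        assert detect_clusters(ids, tiny_catalog, min_genes=2) == []

    def test_one_region_one_event_single_cluster(self):
        catalog = catalog_chain("chr19", "19q13.2", 8)
        ids = [f"G{i}:cnLOH" for i in range(8)]
        (cluster,) = detect_clusters(ids, catalog)
        assert cluster.canon_event == "cnLOH"
        assert len(cluster.feature_ids) == 8
        assert cluster.label == "19q13.2"

    def test_large_gap_splits_chain(self):
        near = catalog_chain("chr7", "7p22.3", 5)
        far = catalog_chain("chr7", "7p21", 5, start=50_000_000,
                            prefix="H")
        ids = [g.symbol + ":loss" for g in near + far]
        found = detect_clusters(ids, near + far, max_gap=1_000_000)
        assert [c.label for c in found] == ["7p22.3", "7p21"]

    def test_band_range_label_spans_first_to_last(self):
        catalog = catalog_chain("chr19", "19q13.2", 4) + catalog_chain(
            "chr19", "19q13.31", 4, start=1_700_000, prefix="H")
        ids = [g.symbol + ":cnLOH" for g in catalog]
        (cluster,) = detect_clusters(ids, catalog)
        assert cluster.label == "19q13.2-19q13.31"

    def test_input_order_invariance(self):
        catalog = catalog_chain("chr16", "16q13", 7)
        ids = [g.symbol + ":loss" for g in catalog]
        assert (detect_clusters(ids, catalog)
                == detect_clusters(ids[::-1], catalog))

    def test_ranking_frame_accepted_and_min_genes_enforced(self):
        catalog = catalog_chain("chr16", "16q13", 4)
        frame = pd.DataFrame(
            {"feature_id": [g.symbol + ":loss" for g in catalog]})
        assert detect_clusters(frame, catalog, min_genes=5) == []
        assert len(detect_clusters(frame, catalog, min_genes=4)) == 1

    def test_missing_gene_rejected(self, tiny_catalog):
        with pytest.raises(ValidationError, match="GHOST"):
            detect_clusters(["GHOST:loss"], tiny_catalog)

    def test_frequency_annotation(self):
        catalog = catalog_chain("chr19", "19q13.2", 2, prefix="F")
        values = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        matrix = __import__("cnaforest").GeneEventMatrix.from_arrays(
            ["S1", "S2"], ["F0:cnLOH", "F1:cnLOH"], values)
        labels = np.array([True, False])
        clusters = detect_clusters(["F0:cnLOH", "F1:cnLOH"], catalog,
                                   min_genes=2)
        (annotated,) = annotate_cluster_frequencies(clusters, matrix, labels)
        assert annotated.freq_mrd_pos == 1.0
        assert annotated.freq_mrd_neg == 0.0


class TestRegionSummary:
    region = GenomicInterval("chr19", 42_500_001, 44_000_000)

    def test_single_segment_collapses_all_stats(self):
        # one cnLOH call of 1045.83 kb, 89 markers, overlapping 22 genes
        seg = make_segment(sample_id="P1", chrom="chr19", start=42_600_001,
                           end=42_600_000 + 1_045_830, event_type="cnLOH",
                           marker_count=89)
        catalog = catalog_chain("chr19", "19q13.2", 22, start=42_610_000,
                                gap=1_000, width=45_000)
        table = region_summary([seg], self.region, "cnLOH", catalog,
                               {"mrd_pos": ["P1"]})
        for stat in ("min", "median", "max"):
            row = table.loc[("mrd_pos", stat)]
            assert row.size_kb == pytest.approx(1045.83)
            assert row.marker_count == 89
            assert row.gene_count == 22

    def test_median_over_three_segments(self):
        segs = [
            make_segment(sample_id=f"P{i}", chrom="chr19",
                         start=42_600_001, end=42_600_000 + mb * 10**6,
                         event_type="cnLOH", marker_count=100 * mb)
            for i, mb in enumerate((1, 2, 3))
        ]
        table = region_summary(segs, self.region, "cnLOH", [],
                               {"g": [s.sample_id for s in segs]})
        assert table.loc[("g", "median")].size_kb == pytest.approx(2000)
        assert table.loc[("g", "min")].size_kb == pytest.approx(1000)
        assert table.loc[("g", "max")].marker_count == 300

    def test_mosaic_losses_qualify_for_loss_regions(self):
        seg = make_segment(sample_id="P1", chrom="chr19",
                           start=42_600_001, end=43_000_000,
                           event_type="loss_mosaic", mosaic_fraction=0.4)
        table = region_summary([seg], self.region, "loss", [],
                               {"g": ["P1"]})
        assert table.loc[("g", "min")].size_kb == pytest.approx(400.0)

    def test_empty_group_error_names_group(self):
        seg = make_segment(sample_id="P1", chrom="chr19",
                           start=42_600_001, end=43_000_000,
                           event_type="cnLOH")
        with pytest.raises(ValidationError, match="reference"):
            region_summary([seg], self.region, "cnLOH", [],
                           {"reference": ["R1"]})


class TestAssociationTable:
    def test_columns_and_adjustment(self):
        matrix, labels = single_feature_matrix(17, 13, 18, 3)
        table = association_table(matrix, labels)
        row = table.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (13, 4, 3, 15)
        assert row.odds_ratio == pytest.approx(16.25)
        assert row.q_adj >= row.p_raw
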