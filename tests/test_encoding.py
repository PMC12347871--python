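"""Gene x event encoding: overlap arithmetic, loss-merging, and
equivalence with a brute-force segment-by-gene oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnaforest import (
    GeneAnnotation,
    GeneEventMatrix,
    GenomicInterval,
    ValidationError,
    canonical_event,
    encode,
    overlaps,
)
from cnaforest.encoding import GeneEventFeature

from .conftest import make_segment

intervals = st.builds(
    lambda chrom, start, length: GenomicInterval(chrom, start,
                                                 start + length),
    st.sampled_from(["chr1", "chr2"]),
    st.integers(1, 10_000),
    st.integers(0, 5_000),
)


def brute_force_encode(segments, catalog, sample_ids):
    """Independent double-loop oracle over all segment x gene pairs."""
    pairs = set()
    for s in segments:
        assert s.sample_id in sample_ids
        for g in catalog:
            if overlaps(s.interval, g.interval):
                pairs.add((s.sample_id, g.symbol,
                           canonical_event(s.event_type)))
    features = sorted({f"{sym}:{ev}" for _, sym, ev in pairs})
    values = np.zeros((len(sample_ids), len(features)), dtype=np.uint8)
    for sid, sym, ev in pairs:
        values[list(sample_ids).index(sid),
               features.index(f"{sym}:{ev}")] = 1
    return features, values


class TestOverlaps:
    def test_single_shared_base(self):
        assert overlaps(GenomicInterval("chr1", 100, 200),
                        GenomicInterval("chr1", 200, 300))

    def test_adjacent_disjoint(self):
        assert not overlaps(GenomicInterval("chr1", 100, 200),
                            GenomicInterval("chr1", 201, 300))

    def test_different_chromosomes_never_overlap(self):
        assert not overlaps(GenomicInterval("chr1", 100, 200),
                            GenomicInterval("chr2", 100, 200))

    @given(intervals, intervals)
    def test_symmetric(self, a, b):
        assert overlaps(a, b) == overlaps(b, a)

    @given(intervals)
    def test_reflexive(self, a):
        assert overlaps(a, a)


class TestCanonicalEvent:
    @pytest.mark.parametrize(
        "raw,expected",
        [("loss_mosaic", "loss"), ("loss", "loss"), ("gain", "gain"),
         ("cnLOH", "cnLOH")],
    )
    def test_merge_rule(self, raw, expected):
        assert canonical_event(raw) == expected

    def test_unknown_event_rejected(self):
        with pytest.raises(ValidationError):
            canonical_event("inversion")


class TestEncode:
    def test_loss_segment_sets_gene_loss_feature(self, tiny_catalog):
        seg = make_segment(chrom="chr1", start=1_000_000, end=1_100_000)
        m = encode([seg], tiny_catalog, ["P001"])
        assert m.feature_ids == ["A0:loss"]
        assert m.values[0, 0] == 1

    def test_mosaic_loss_lands_in_same_column(self, tiny_catalog):
        clonal = make_segment(chrom="chr1", start=1_000_000, end=1_100_000)
        mosaic = make_segment(sample_id="P002", chrom="chr1",
                              start=1_000_000, end=1_100_000,
                              event_type="loss_mosaic",
                              mosaic_fraction=0.37)
        m = encode([clonal, mosaic], tiny_catalog, ["P001", "P002"])
        assert m.feature_ids == ["A0:loss"]
        assert m.values.tolist() == [[1], [1]]

    def test_sample_without_overlaps_has_zero_row(self, tiny_catalog):
        seg = make_segment(chrom="chr1", start=1_000_000, end=1_100_000)
        m = encode([seg], tiny_catalog, ["P001", "P002"])
        assert m.values[1].sum() == 0

    def test_loss_and_cnloh_on_one_gene_set_both_columns(self, tiny_catalog):
        loss = make_segment(chrom="chr1", start=1_000_000, end=1_100_000)
        loh = make_segment(chrom="chr1", start=1_000_000, end=1_100_000,
                           event_type="cnLOH")
        m = encode([loss, loh], tiny_catalog, ["P001"])
        assert m.feature_ids == ["A0:cnLOH", "A0:loss"]
        assert m.values.tolist() == [[1, 1]]

    def test_unknown_sample_rejected(self, tiny_catalog):
        with pytest.raises(ValidationError, match="P001"):
            encode([make_segment()], tiny_catalog, ["OTHER"])

    def test_order_invariance_and_duplicate_idempotence(self, tiny_catalog):
        segs = [
            make_segment(chrom="chr1", start=900_000, end=1_400_000),
            make_segment(chrom="chr2", start=5_000_000, end=6_000_000,
                         event_type="cnLOH"),
            make_segment(sample_id="P002", chrom="chr2", start=5_200_000,
                         end=5_300_000, event_type="gain",
                         mean_log2ratio=0.4),
        ]
        ids = ["P001", "P002"]
        base = encode(segs, tiny_catalog, ids)
        shuffled = encode(segs[::-1], tiny_catalog[::-1], ids)
        doubled = encode(segs + segs, tiny_catalog, ids)
        for other in (shuffled, doubled):
            assert other.feature_ids == base.feature_ids
            assert np.array_equal(other.values, base.values)

    def test_monotone_adding_segment_never_clears_entries(self, tiny_catalog):
        segs = [make_segment(chrom="chr1", start=900_000, end=1_400_000)]
        extra = make_segment(sample_id="P002", chrom="chr2",
                             start=5_000_000, end=7_000_000)
        before = encode(segs, tiny_catalog, ["P001", "P002"]).to_frame()
        after = encode(segs + [extra], tiny_catalog,
                       ["P001", "P002"]).to_frame()
        assert (after[before.columns] >= before).all().all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        catalog = []
        for k in range(150):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(1, 3_000_000))
            catalog.append(GeneAnnotation(
                f"G{k}", GenomicInterval(chrom, start,
                                         start + int(rng.integers(1, 80_000))),
                "1q11"))
        sample_ids = [f"S{i}" for i in range(12)]
        segments = []
        for _ in range(120):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(1, 3_000_000))
            ev = ("gain", "loss", "loss_mosaic", "cnLOH")[rng.integers(4)]
            segments.append(make_segment(
                sample_id=sample_ids[rng.integers(12)], chrom=chrom,
                start=start, end=start + int(rng.integers(1, 400_000)),
                event_type=ev))
        m = encode(segments, catalog, sample_ids)
        feats, values = brute_force_encode(segments, catalog, sample_ids)
        assert m.feature_ids == feats
        assert np.array_equal(m.values, values)


class TestMatrixContainer:
    def test_entries_must_be_binary(self):
        with pytest.raises(ValidationError):
            GeneEventMatrix.from_arrays(["S1"], ["A:loss"], [[2]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            GeneEventMatrix.from_arrays(["S1", "S1"], ["A:loss"],
                                        [[1], [0]])

    def test_constant_columns_flagged_not_forbidden(self):
        m = GeneEventMatrix.from_arrays(
            ["S1", "S2"], ["A:loss", "B:gain"], [[1, 1], [1, 0]]
        )
        assert m.constant_feature_ids() == ["A:loss"]

    def test_feature_id_round_trip(self):
        feat = GeneEventFeature.from_id("PSG8-AS1:cnLOH")
        assert feat.symbol == "PSG8-AS1"
        assert feat.canon_event == "cnLOH"
        assert feat.id == "PSG8-AS1:cnLOH"

    def test_wide_round_trip(self, tmp_path):
        m = GeneEventMatrix.from_arrays(
            ["S1", "S2"], ["A:loss", "B:gain"], [[1, 0], [0, 1]]
        )
        m.write_wide(tmp_path / "m.tsv")
        back = GeneEventMatrix.read_wide(tmp_path / "m.tsv")
        assert back.sample_ids == m.sample_ids
        assert back.feature_ids == m.feature_ids
        assert np.array_equal(back.values, m.values)
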