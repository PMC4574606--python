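"""Allele counting semantics: filters, dedup, mate overlap, accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aekit.allele_counting import (
    CountingOptions,
    SiteCounts,
    count_alleles,
    read_counts_table,
    resolve_fragment_overlap,
    select_duplicate_representative,
    write_counts_table,
)
from aekit.variant_io import HetSite

from conftest import bam_from_sam

SITE = HetSite("chr1", 100, "A", "G")


class TestOptions:
    def test_mapping_score_policy_rejected(self):
        with pytest.raises(ValueError, match="mapping score"):
            CountingOptions(duplicate_policy="by_mapping_score")

    def test_negative_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CountingOptions(min_base_quality=-1)


class TestHandPileup:
    """Counts on the hand-written 20-record SAM match the by-hand tally."""

    def test_default_filtering_cascade(self, hand_bam):
        (c,) = count_alleles(hand_bam, [SITE])
        assert (c.ref_count, c.alt_count, c.other_count) == (5, 3, 2)
        assert c.total_count == 8
        assert c.raw_depth == 16
        assert c.low_mapq_dropped == 1
        assert c.low_baseq_dropped == 1
        assert c.duplicates_dropped == 1
        assert c.mate_conflicts_dropped == 2
        assert c.overlapping_mates_merged == 1
        assert c.improper_pairs == 1
        assert c.accounted() == c.raw_depth

    def test_keep_duplicates(self, hand_bam):
        (c,) = count_alleles(
            hand_bam, [SITE], CountingOptions(remove_duplicates=False)
        )
        assert c.ref_count == 6  # the flagged duplicate 'A' read is counted
        assert c.duplicates_dropped == 0

    def test_no_fragment_merge_counts_both_mates(self, hand_bam):
        (c,) = count_alleles(
            hand_bam, [SITE], CountingOptions(count_fragments_once=False)
        )
        # p1 contributes two 'G'; p2's conflicting A and G are both counted
        assert c.alt_count == 3 + 2  # r4, r5, p1 twice, p2's G
        assert c.ref_count == 5 + 1  # plus p2's A
        assert c.mate_conflicts_dropped == 0
        assert c.overlapping_mates_merged == 0
        assert c.accounted() == c.raw_depth

    def test_quality_threshold_monotonicity(self, hand_bam):
        """Raising either quality threshold never increases any allele count."""
        prev = None
        for bq, mq in [(0, 0), (10, 20), (41, 20), (41, 61)]:
            (c,) = count_alleles(
                hand_bam, [SITE], CountingOptions(min_base_quality=bq, min_mapping_quality=mq)
            )
            if prev is not None:
                assert c.ref_count <= prev.ref_count
                assert c.alt_count <= prev.alt_count
                assert c.other_count <= prev.other_count
            assert c.accounted() == c.raw_depth
            prev = c

    def test_zero_coverage_site_reported(self, hand_bam):
        counts = count_alleles(hand_bam, [SITE, HetSite("chr1", 5000, "A", "G")])
        assert counts[1].raw_depth == 0 and counts[1].total_count == 0

    def test_min_depth_omits_shallow_sites(self, hand_bam):
        counts = count_alleles(
            hand_bam,
            [SITE, HetSite("chr1", 5000, "A", "G")],
            CountingOptions(min_depth=1),
        )
        assert [c.site.pos for c in counts] == [100]

    def test_unknown_chromosome_errors(self, hand_bam):
        with pytest.raises(ValueError, match="chrUn"):
            count_alleles(hand_bam, [HetSite("chrUn", 100, "A", "G")])

    def test_unindexed_input_errors(self, hand_bam, tmp_path):
        bare = tmp_path / "bare.bam"
        bare.write_bytes(hand_bam.read_bytes())  # no .bai alongside
        with pytest.raises(ValueError, match="indexed"):
            count_alleles(bare, [SITE])


class TestFragmentOverlap:
    def test_consistent_mates_count_once_at_max_quality(self):
        assert resolve_fragment_overlap("A", 30, "A", 20) == ("A", 30)

    def test_conflicting_mates_discarded(self):
        assert resolve_fragment_overlap("A", 30, "G", 30) is None

    def test_max_quality_rescues_low_quality_mate(self, tmp_path):
        """A fragment whose mates read A@30 and A@5 passes a min-BQ of 10:
        the consensus carries the higher quality."""
        sam = "\n".join(
            [
                "@HD\tVN:1.6\tSO:unsorted",
                "@SQ\tSN:chr1\tLN:10000",
                "q1\t99\tchr1\t96\t60\t10M\t=\t98\t12\tCCCCACCCCC\t??????????",
                "q1\t147\tchr1\t98\t60\t10M\t=\t96\t-12\tCCACCCCCCC\t&&&&&&&&&&",
                "",
            ]
        )  # '?' = Q30, '&' = Q5
        bam = bam_from_sam(sam, tmp_path, "pair")
        (c,) = count_alleles(bam, [SITE], CountingOptions(min_base_quality=10))
        assert (c.ref_count, c.low_baseq_dropped, c.overlapping_mates_merged) == (1, 0, 1)

    @given(
        b1=st.sampled_from("ACGT"),
        b2=st.sampled_from("ACGT"),
        q1=st.integers(0, 60),
        q2=st.integers(0, 60),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetric_and_quality_max(self, b1, b2, q1, q2):
        res = resolve_fragment_overlap(b1, q1, b2, q2)
        assert res == resolve_fragment_overlap(b2, q2, b1, q1)
        if b1 == b2:
            assert res == (b1, max(q1, q2))
        else:
            assert res is None


class _Read:
    def __init__(self, base, quality):
        self.base = base
        self.site_base_quality = quality


class TestDuplicateRepresentative:
    def test_singleton_returned(self):
        r = _Read("A", 40)
        assert select_duplicate_representative([r], "random", seed=1) is r
        assert select_duplicate_representative([r], "by_base_quality", seed=1) is r

    def test_by_base_quality_argmax(self):
        group = [_Read("A", 40), _Read("G", 20), _Read("A", 10)]
        rep = select_duplicate_representative(group, "by_base_quality", seed=3)
        assert rep is group[0]

    def test_deterministic_under_seed(self):
        group = [_Read("A", 30), _Read("G", 30), _Read("C", 30)]
        picks = {select_duplicate_representative(group, "random", seed=11).base for _ in range(5)}
        assert len(picks) == 1

    def test_random_policy_unbiased(self):
        """REF retained at the group REF frequency: 50 % +/- 1.5 % over
        10 000 seeded draws from a balanced REF/ALT duplicate pair."""
        group = [_Read("A", 30), _Read("G", 30)]
        rng = np.random.default_rng(7)
        kept_ref = sum(
            select_duplicate_representative(group, "random", rng=rng).base == "A"
            for _ in range(10_000)
        )
        assert abs(kept_ref / 10_000 - 0.5) < 0.015


class TestSignatureDedup:
    def test_signature_mode_collapses_unmarked_duplicates(self, tmp_path):
        """Two single-end reads with identical coordinates but no duplicate
        flag collapse to one under signature detection, not under flag."""
        sam = "\n".join(
            [
                "@HD\tVN:1.6\tSO:unsorted",
                "@SQ\tSN:chr1\tLN:10000",
                "d1\t0\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCACCCCC\tIIIIIIIIII",
                "d2\t0\tchr1\t96\t60\t10M\t*\t0\t0\tCCCCACCCCC\tIIIIIIIIII",
                "",
            ]
        )
        bam = bam_from_sam(sam, tmp_path, "sig")
        (by_flag,) = count_alleles(bam, [SITE], CountingOptions(duplicate_detection="flag"))
        (by_sig,) = count_alleles(
            bam, [SITE], CountingOptions(duplicate_detection="signature")
        )
        assert by_flag.ref_count == 2
        assert (by_sig.ref_count, by_sig.duplicates_dropped) == (1, 1)
        assert by_sig.accounted() == by_sig.raw_depth


class TestCountsTable:
    def test_write_then_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = []
        for i in range(50):
            ref, alt = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            other = int(rng.integers(0, 3))
            counts.append(
                SiteCounts(
                    site=HetSite("chr1", 100 + i * 10, "A", "G", site_id=f"s{i}"),
                    ref_count=ref,
                    alt_count=alt,
                    other_count=other,
                    raw_depth=ref + alt + other + 2,
                    low_baseq_dropped=1,
                    low_mapq_dropped=1,
                    improper_pairs=int(rng.integers(0, 2)),
                )
            )
        path = tmp_path / "counts.tsv"
        write_counts_table(counts, path)
        assert read_counts_table(path) == counts

    def test_schema_and_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_counts_table([], path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header[:13] == [
            "contig", "position", "variantID", "refAllele", "altAllele",
            "refCount", "altCount", "totalCount", "lowMAPQDepth",
            "lowBaseQDepth", "rawDepth", "otherBases", "improperPairs",
        ]
        assert read_counts_table(path) == []

    def test_total_count_column(self, tmp_path):
        path = tmp_path / "one.tsv"
        write_counts_table(
            [SiteCounts(site=SITE, ref_count=3, alt_count=2, raw_depth=5)], path
        )
        lines = path.read_text().splitlines()
        row = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
        assert row["totalCount"] == "5"
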