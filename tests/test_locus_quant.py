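import numpy as np
import pytest

from rcre_kit import oracles, synth
from rcre_kit.io_formats import AlignmentRecord, GenomicInterval, read_alignments
from rcre_kit.locus_quant import (
    FilterConfig,
    coverage_track,
    count_fragments,
    filter_unique_pairs,
)
from rcre_kit.synth import SimAlignmentSpec, SimLocus, loci_annotation


def _pair(qname, chrom="chr1", start=100, end=350, tags1=None, tags2=None,
          proper=True, r1_reverse=True):
    r1 = AlignmentRecord(qname, GenomicInterval(chrom, end - 75, end,
                                                "-" if r1_reverse else "+"),
                         paired=True, proper_pair=proper,
                         reverse_strand=r1_reverse, first_in_pair=True,
                         tags=tags1 or {})
    r2 = AlignmentRecord(qname, GenomicInterval(chrom, start, start + 75,
                                                "+" if r1_reverse else "-"),
                         paired=True, proper_pair=proper,
                         reverse_strand=not r1_reverse, first_in_pair=False,
                         tags=tags2 or {})
    return [r1, r2]


class TestFilterUniquePairs:
    def test_clean_proper_pair_is_kept(self):
        kept, stats = filter_unique_pairs(_pair("f1"))
        assert len(kept) == 2
        assert stats.n_kept == 2 and stats.n_input == 2

    def test_one_tagged_mate_removes_both(self):
        kept, stats = filter_unique_pairs(_pair("f1", tags1={"ZS": "40"}))
        assert kept == []
        assert stats.n_multihit == 2

    def test_unpaired_read_removed_as_not_proper(self):
        rec = AlignmentRecord("solo", GenomicInterval("chr1", 0, 75))
        kept, stats = filter_unique_pairs([rec])
        assert kept == [] and stats.n_not_proper == 1

    def test_secondary_records_removed(self):
        recs = _pair("f1")
        sec = AlignmentRecord("f1", GenomicInterval("chr1", 500, 575),
                              paired=True, proper_pair=True, secondary=True,
                              first_in_pair=True)
        kept, stats = filter_unique_pairs(recs + [sec])
        assert len(kept) == 2 and stats.n_secondary == 1

    def test_configurable_tag(self):
        kept, _ = filter_unique_pairs(_pair("f1", tags1={"XS": "1"}),
                                      FilterConfig(multihit_tag="XS"))
        assert kept == []

    def test_stats_categories_sum_to_input(self, two_locus_sim):
        _, _, sam_text, _ = two_locus_sim
        recs = [r for r in _read_sam_text(sam_text)]
        _, stats = filter_unique_pairs(recs)
        stats.check()

    def test_equivalent_to_literal_command_semantics(self, two_locus_sim):
        _, _, sam_text, _ = two_locus_sim
        recs = list(_read_sam_text(sam_text))
        kept, _ = filter_unique_pairs(recs)
        literal = oracles.literal_sam_filter(sam_text)
        assert len(kept) == len(literal)
        assert sorted(r.qname for r in kept) == sorted(l.split("\t")[0] for l in literal)


def _read_sam_text(sam_text, tmpdir="/tmp"):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        p = Path(d) / "x.sam"
        p.write_text(sam_text)
        yield from read_alignments(p)


class TestCountFragments:
    @pytest.fixture
    def loci(self):
        return loci_annotation([
            SimLocus("L", "chr1", 0, 2_000, "+"),
            SimLocus("M", "chr1", 1_900, 4_000, "+"),  # overlaps L's tail
        ])

    def test_reverse_stranded_fragments_counted(self, loci):
        recs = sum((_pair(f"f{i}", start=500, end=800) for i in range(3)), [])
        lc = count_fragments(recs, loci, "reverse")
        assert lc.counts["L"] == 3
        assert lc.n_assigned == 3

    def test_fragment_spanning_two_loci_is_ambiguous(self, loci):
        recs = _pair("amb", start=1_850, end=2_100)
        lc = count_fragments(recs, loci, "reverse")
        assert lc.counts.sum() == 0 and lc.n_ambiguous == 1

    def test_wrong_orientation_dropped_only_when_stranded(self, loci):
        recs = _pair("f1", start=500, end=800, r1_reverse=False)  # antisense fragment
        assert count_fragments(recs, loci, "reverse").counts["L"] == 0
        assert count_fragments(recs, loci, "reverse").n_wrong_strand == 1
        assert count_fragments(recs, loci, "unstranded").counts["L"] == 1

    def test_empty_locus_set_rejected(self):
        from rcre_kit.io_formats import AnnotationSet

        with pytest.raises(ValueError):
            count_fragments([], AnnotationSet())

    def test_sum_conservation(self, two_locus_sim):
        loci_spec, _, sam_text, _ = two_locus_sim
        recs = list(_read_sam_text(sam_text))
        kept, _ = filter_unique_pairs(recs)
        lc = count_fragments(kept, loci_annotation(loci_spec))
        n_fragments = len({r.qname for r in kept})
        assert lc.n_assigned + lc.n_ambiguous + lc.n_unassigned + lc.n_wrong_strand \
            == n_fragments

    def test_matches_brute_force_oracle(self, two_locus_sim):
        loci_spec, spec, sam_text, _ = two_locus_sim
        recs = list(_read_sam_text(sam_text))
        kept, _ = filter_unique_pairs(recs)
        lc = count_fragments(kept, loci_annotation(loci_spec), "reverse")
        by_name = {}
        for r in kept:
            by_name.setdefault(r.qname, []).append(r)
        fragments = []
        for mates in by_name.values():
            r1 = next(m for m in mates if m.first_in_pair)
            start = min(m.interval.start for m in mates)
            end = max(m.interval.end for m in mates)
            tstrand = "+" if r1.reverse_strand else "-"  # dUTP rule
            fragments.append((r1.interval.chrom, start, end, tstrand))
        expected = oracles.brute_force_fragment_counts(
            fragments,
            [(l.id, l.chrom, l.start, l.end, l.strand) for l in loci_spec],
            "reverse",
        )
        assert lc.counts.to_dict() == expected

    def test_simulated_truth_recovery_end_to_end(self, two_locus_sim, tmp_path):
        loci_spec, _, sam_text, truth = two_locus_sim
        p = tmp_path / "sim.sam"
        p.write_text(sam_text)
        kept, _ = filter_unique_pairs(read_alignments(p))
        lc = count_fragments(kept, loci_annotation(loci_spec), "reverse")
        assert lc.counts.to_dict() == truth


class TestCoverageTrack:
    def test_single_fragment_fpkm_formula(self):
        recs = _pair("f1", start=0, end=150)  # covers bins 0..2 at width 50
        track = coverage_track(recs, bin_width=50, total_kept=10**6)
        assert track.bins["chr1"][0] == pytest.approx(1e9 / (50 * 1e6)) == 20.0

    def test_no_fragments_is_all_zero(self):
        track = coverage_track([], bin_width=50, total_kept=10,
                               chrom_lengths={"chr1": 500})
        assert track.bins["chr1"] == [0.0] * 10

    def test_duplication_with_doubled_total_is_invariant(self):
        recs = _pair("f1", start=100, end=400)
        once = coverage_track(recs, bin_width=50, total_kept=1000)
        twice = coverage_track(recs + _pair("f2", start=100, end=400),
                               bin_width=50, total_kept=2000)
        assert once.bins == twice.bins

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            coverage_track([], bin_width=50, total_kept=0)
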