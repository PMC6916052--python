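"""Unique-fragment quantification of repetitive proviral loci.

Multi-copy proviral loci share near-identical sequence, so a read pair is
only trusted when the aligner reported no scored secondary hit.  The filter
keeps proper pairs, drops secondary/supplementary records, and drops any
fragment either of whose mates carries the multi-hit tag (``ZS`` for
HISAT2; configurable).  Surviving fragments are assigned to loci by overlap
of the mate-pair union interval under a strandedness rule, with fragments
touching two loci discarded as ambiguous.  Normalized coverage tracks
(fragments per kilobase per million kept fragments) are emitted as bedGraph.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import AlignmentRecord, AnnotationSet, GenomicInterval

STRANDEDNESS_MODES = ("unstranded", "forward", "reverse")


@dataclass(frozen=True)
class FilterConfig:
    """Which alignments count as uniquely mapped proper pairs.

    ``multihit_tag``: presence of this optional tag marks an alignment with a
    scored secondary hit, i.e. a non-unique mapping (HISAT2 writes ``ZS``;
    bowtie2-style output would use ``XS``).
    """

    multihit_tag: str = "ZS"

    def __post_init__(self) -> None:
        if not self.multihit_tag:
            raise ValueError("multihit_tag must be non-empty")


@dataclass
class FilterStats:
    n_input: int = 0
    n_not_proper: int = 0
    n_multihit: int = 0
    n_secondary: int = 0
    n_kept: int = 0

    def check(self) -> None:
        assert self.n_input == (
            self.n_kept + self.n_not_proper + self.n_multihit + self.n_secondary
        )

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


def filter_unique_pairs(
    records: Iterable[AlignmentRecord], config: FilterConfig | None = None
) -> tuple[list[AlignmentRecord], FilterStats]:
    """Keep uniquely-mapped proper pairs; drop the rest, with accounting.

    Removal categories are assigned with priority secondary/supplementary >
    not-proper-pair > multihit, so every input record lands in exactly one
    bucket.  Pair consistency is enforced: if either mate of a fragment
    carries the multihit tag, both mates are removed.
    """
    config = config or FilterConfig()
    stats = FilterStats()
    primary: list[AlignmentRecord] = []
    tagged_fragments: set[str] = set()
    for rec in records:
        stats.n_input += 1
        if rec.secondary or rec.supplementary:
            stats.n_secondary += 1
            continue
        if not rec.proper_pair:
            stats.n_not_proper += 1
            continue
        if config.multihit_tag in rec.tags:
            tagged_fragments.add(rec.qname)
        primary.append(rec)
    kept: list[AlignmentRecord] = []
    for rec in primary:
        if rec.qname in tagged_fragments:
            stats.n_multihit += 1
        else:
            kept.append(rec)
    stats.n_kept = len(kept)
    stats.check()
    return kept, stats


@dataclass
class LocusCounts:
    """Per-locus fragment counts for one sample."""

    counts: pd.Series
    strandedness: str
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0
    n_wrong_strand: int = 0
    n_unpaired_dropped: int = 0


def _fragment_strand(read1: AlignmentRecord, strandedness: str) -> str | None:
    """Sense strand of the transcript a fragment came from, per library type.

    In a dUTP ('reverse') library the first-in-pair read is antisense to the
    transcript; in a 'forward' library it is sense.
    """
    if strandedness == "unstranded":
        return None
    r1_strand = "-" if read1.reverse_strand else "+"
    if strandedness == "forward":
        return r1_strand
    return "+" if r1_strand == "-" else "-"


def _pair_fragments(records: Iterable[AlignmentRecord]):
    """Group primary records into (read1, read2) fragments keyed by qname."""
    by_name: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_name.setdefault(rec.qname, []).append(rec)
    fragments = []
    n_unpaired = 0
    for qname in by_name:
        mates = by_name[qname]
        if len(mates) != 2:
            n_unpaired += 1
            continue
        r1 = next((m for m in mates if m.first_in_pair), mates[0])
        r2 = mates[1] if r1 is mates[0] else mates[0]
        fragments.append((qname, r1, r2))
    return fragments, n_unpaired


def count_fragments(
    records: Iterable[AlignmentRecord],
    loci: AnnotationSet,
    strandedness: str = "reverse",
) -> LocusCounts:
    """Assign filtered fragments to proviral loci and count them.

    A fragment's union interval (min start to max end of its mates) must
    overlap a locus by at least one nucleotide, and its inferred transcript
    strand must match the locus strand under the strandedness rule
    ('reverse' is the dUTP default).  Fragments overlapping two or more loci
    are discarded as ambiguous; each fragment contributes to at most one
    locus.
    """
    if strandedness not in STRANDEDNESS_MODES:
        raise ValueError(f"strandedness must be one of {STRANDEDNESS_MODES}")
    locus_features = loci.of_kind("locus")
    if not locus_features:
        raise ValueError("locus annotation set is empty")
    counts = pd.Series(0, index=pd.Index([f.id for f in locus_features], name="locus_id"))
    out = LocusCounts(counts, strandedness)
    fragments, out.n_unpaired_dropped = _pair_fragments(records)
    for _qname, r1, r2 in fragments:
        if r1.interval.chrom != r2.interval.chrom:
            out.n_unassigned += 1
            continue
        union = GenomicInterval(
            r1.interval.chrom,
            min(r1.interval.start, r2.interval.start),
            max(r1.interval.end, r2.interval.end),
        )
        overlapping = loci.query(union, kind="locus")
        if not overlapping:
            out.n_unassigned += 1
            continue
        if len(overlapping) > 1:
            out.n_ambiguous += 1
            continue
        locus = overlapping[0]
        frag_strand = _fragment_strand(r1, strandedness)
        if frag_strand is not None and locus.interval.strand in "+-" \
                and frag_strand != locus.interval.strand:
            out.n_wrong_strand += 1
            continue
        counts[locus.id] += 1
        out.n_assigned += 1
    return out


@dataclass
class CoverageTrack:
    """Fixed-width binned, depth-normalized fragment coverage per chromosome.

    Bin values are fragments-per-kilobase-per-million-kept: overlapping
    fragment count x 1e9 / (bin_width x total kept fragments).
    """

    bin_width: int
    bins: dict[str, list[float]] = field(default_factory=dict)


def coverage_track(
    records: Iterable[AlignmentRecord],
    bin_width: int = 50,
    total_kept: int | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> CoverageTrack:
    """Normalized fragment coverage in fixed-width bins.

    ``total_kept`` defaults to the number of fragments in ``records``; it is
    the library-size denominator and must be positive.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    fragments, _ = _pair_fragments(records)
    if total_kept is None:
        total_kept = len(fragments)
    if total_kept <= 0:
        raise ValueError("total_kept must be positive")
    raw: dict[str, dict[int, int]] = {}
    max_bin: dict[str, int] = {}
    for _qname, r1, r2 in fragments:
        if r1.interval.chrom != r2.interval.chrom:
            continue
        chrom = r1.interval.chrom
        start = min(r1.interval.start, r2.interval.start)
        end = max(r1.interval.end, r2.interval.end)
        first_bin, last_bin = start // bin_width, (end - 1) // bin_width
        per = raw.setdefault(chrom, {})
        for b in range(first_bin, last_bin + 1):
            per[b] = per.get(b, 0) + 1
        max_bin[chrom] = max(max_bin.get(chrom, 0), last_bin)
    track = CoverageTrack(bin_width)
    scale = 1e9 / (bin_width * total_kept)
    for chrom in raw:
        n_bins = max_bin[chrom] + 1
        if chrom_lengths and chrom in chrom_lengths:
            n_bins = max(n_bins, math.ceil(chrom_lengths[chrom] / bin_width))
        track.bins[chrom] = [raw[chrom].get(b, 0) * scale for b in range(n_bins)]
    if chrom_lengths:
        for chrom, length in chrom_lengths.items():
            track.bins.setdefault(chrom, [0.0] * math.ceil(length / bin_width))
    return track
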