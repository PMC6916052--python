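"""Scanning a genome for degenerate copies of a query element.

The scanner finds, on both strands, every region whose global-alignment
identity to the query element meets a percent-identity threshold (94% by
default, the cutoff used to call RcRE-like sequences).  It is a classic
seed-and-extend design: exact k-mer seeds locate candidate diagonals, each
candidate window of roughly query length is aligned semi-globally
(query end-to-end, window overhangs free), and the surviving hits are
reduced to a non-overlapping set by greedy best-score selection.

Percent identity follows the BLAST convention: identical columns divided by
total alignment columns, gap columns counting as non-identity.  ``N`` bases
never match anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GenomeSequence, GenomicInterval, reverse_complement


@dataclass(frozen=True)
class QueryElement:
    """The prototype element searched for (e.g. a ~433-nt RcRE)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 50:
            raise ValueError("query element must be at least 50 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("query element alphabet is {A,C,G,T}")


@dataclass(frozen=True)
class ScanParams:
    """Alignment scoring and seeding parameters.

    BLASTN-like defaults: match +2, mismatch -3, gap open -5, gap extend -2.
    ``seed_k`` is the exact-match seed length; ``window_slop`` widens the
    candidate window to query length x (1 + slop) on each side.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    seed_k: int = 12
    window_slop: float = 0.10


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    n_match: int
    n_columns: int
    score: float

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.n_match / self.n_columns


@dataclass(frozen=True)
class MismatchPosition:
    column: int
    ref_char: str  # '-' for an insertion relative to the reference
    alt_char: str  # '-' for a deletion


@dataclass(frozen=True)
class MismatchTrack:
    """Alignment columns at which a sequence differs from the reference.

    The machine-readable form of a highlighter plot: one entry per
    mismatching column, carrying the substitution (or gap) observed.
    """

    sequence_id: str
    n_columns: int
    positions: tuple[MismatchPosition, ...]


@dataclass(frozen=True)
class ElementHit:
    """A located degenerate copy of the query element."""

    interval: GenomicInterval
    identity_pct: float
    score: float
    alignment: PairwiseAlignment
    hit_sequence: str  # query-strand oriented

    @property
    def strand(self) -> str:
        return self.interval.strand


def _make_aligner(params: ScanParams, free_target_ends: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # explicit ACGTN matrix so that N never matches anything, itself included
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if x == y and x != "N":
                matrix[x, y] = params.match
            else:
                matrix[x, y] = params.mismatch
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if free_target_ends:
        # free end gaps in the target row: query aligns end-to-end inside
        # the window, window overhangs cost nothing
        aligner.end_deletion_score = 0.0
    return aligner


def _column_stats(a: str, b: str) -> tuple[int, int]:
    n_match = sum(1 for x, y in zip(a, b) if x == y and x != "-" and x != "N")
    return n_match, len(a)


def global_align(a: str, b: str, params: ScanParams | None = None) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch global alignment of two DNA strings.

    Identity is identical columns over total columns x 100; gap and N
    columns count as non-identity.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    params = params or ScanParams()
    aligner = _make_aligner(params)
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    n_match, n_columns = _column_stats(sa, sb)
    return PairwiseAlignment(sa, sb, n_match, n_columns, float(aln.score))


def highlighter(reference: str, others: Sequence[str], ids: Sequence[str] | None = None,
                params: ScanParams | None = None) -> list[MismatchTrack]:
    """Mismatch tracks of each sequence globally aligned to a reference.

    One track per input sequence, in order; an identical sequence yields an
    empty track.
    """
    if ids is None:
        ids = [f"seq{i + 1}" for i in range(len(others))]
    tracks = []
    for sid, seq in zip(ids, others):
        aln = global_align(reference, seq, params)
        positions = tuple(
            MismatchPosition(col, x, y)
            for col, (x, y) in enumerate(zip(aln.aligned_a, aln.aligned_b))
            if x != y or x == "N"
        )
        tracks.append(MismatchTrack(sid, aln.n_columns, positions))
    return tracks


# ---------------------------------------------------------------------------
# Genome scanning
# ---------------------------------------------------------------------------

def _seed_windows(contig: str, query: str, k: int, slop: int) -> list[tuple[int, int]]:
    """Candidate (start, end) windows on the contig from exact k-mer seeds.

    Each seed match implies a diagonal start; nearby diagonal starts are
    clustered into one window padded by ``slop`` on each side.
    """
    qlen = len(query)
    kmer_offsets: dict[str, list[int]] = {}
    for i in range(qlen - k + 1):
        kmer_offsets.setdefault(query[i : i + k], []).append(i)
    starts: list[int] = []
    for p in range(len(contig) - k + 1):
        offsets = kmer_offsets.get(contig[p : p + k])
        if offsets:
            starts.extend(p - off for off in offsets)
    if not starts:
        return []
    starts.sort()
    windows: list[tuple[int, int]] = []
    cluster_lo = cluster_hi = starts[0]
    for s in starts[1:]:
        if s - cluster_hi <= slop:
            cluster_hi = s
        else:
            windows.append((cluster_lo, cluster_hi))
            cluster_lo = cluster_hi = s
    windows.append((cluster_lo, cluster_hi))
    return [
        (max(0, lo - slop), min(len(contig), hi + qlen + slop))
        for lo, hi in windows
    ]


def _align_window(contig: str, win_start: int, win_end: int, query: str,
                  params: ScanParams) -> tuple[int, int, float, int, int] | None:
    """Semi-globally align the query inside a window.

    Returns (start, end, score, n_match, n_columns) in contig coordinates for
    the query-spanning part of the alignment, or None for a degenerate case.
    """
    window = contig[win_start:win_end]
    aligner = _make_aligner(params, free_target_ends=True)
    aln = aligner.align(window, query)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim target-only overhang columns (query gap at either end)
    lo = 0
    while lo < len(sb) and sb[lo] == "-":
        lo += 1
    hi = len(sb)
    while hi > lo and sb[hi - 1] == "-":
        hi -= 1
    if hi <= lo:
        return None
    n_match, n_columns = _column_stats(sa[lo:hi], sb[lo:hi])
    target_start = win_start + lo - sa[:lo].count("-")
    target_len = sum(1 for c in sa[lo:hi] if c != "-")
    if target_len == 0:
        return None
    return target_start, target_start + target_len, float(aln.score), n_match, n_columns


def scan_genome(genome: Iterable[GenomeSequence], query: QueryElement,
                threshold: float = 94.0, params: ScanParams | None = None) -> list[ElementHit]:
    """Find non-overlapping degenerate copies of ``query`` on both strands.

    Every returned hit has global-alignment identity >= ``threshold`` percent
    and length within the seeding tolerance of the query length.  Overlapping
    candidates are resolved greedily by alignment score, ties broken by
    leftmost coordinate then plus strand.  Deterministic for fixed inputs.
    """
    if not (50.0 < threshold <= 100.0):
        raise ValueError("identity threshold must be in (50, 100]")
    params = params or ScanParams()
    genome = list(genome)
    if not genome:
        raise ValueError("genome is empty")
    qlen = len(query.sequence)
    if all(len(g) < qlen for g in genome):
        raise ValueError("query is longer than every contig")
    slop = max(4, int(round(params.window_slop * qlen)))

    candidates: list[ElementHit] = []
    for contig in genome:
        for strand, qseq in (("+", query.sequence), ("-", reverse_complement(query.sequence))):
            for win_start, win_end in _seed_windows(contig.residues, qseq, params.seed_k, slop):
                placed = _align_window(contig.residues, win_start, win_end, qseq, params)
                if placed is None:
                    continue
                start, end, score, n_match, n_columns = placed
                identity = 100.0 * n_match / n_columns
                if identity < threshold:
                    continue
                if abs((end - start) - qlen) > slop:
                    continue
                genomic = contig.residues[start:end]
                oriented = genomic if strand == "+" else reverse_complement(genomic)
                alignment = global_align(query.sequence, oriented, params)
                candidates.append(
                    ElementHit(
                        interval=GenomicInterval(contig.name, start, end, strand),
                        identity_pct=alignment.identity_pct,
                        score=score,
                        alignment=alignment,
                        hit_sequence=oriented,
                    )
                )

    # greedy best-score selection of non-overlapping hits
    candidates.sort(key=lambda h: (-h.score, h.interval.chrom, h.interval.start,
                                   0 if h.strand == "+" else 1))
    selected: list[ElementHit] = []
    for hit in candidates:
        if all(not hit.interval.overlaps(s.interval) for s in selected):
            if hit.identity_pct >= threshold:
                selected.append(hit)
    selected.sort(key=lambda h: (h.interval.chrom, h.interval.start))
    return selected


def hits_to_bed_rows(hits: Sequence[ElementHit], name_prefix: str = "hit"):
    """BED6 rows for a hit list; score = identity x 10, rounded."""
    return [
        (h.interval, f"{name_prefix}{i + 1}", round(h.identity_pct * 10))
        for i, h in enumerate(hits)
    ]
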