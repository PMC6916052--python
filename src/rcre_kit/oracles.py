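"""Independent cross-check implementations.

These deliberately share no code with the pipeline proper: the exhaustive
scanner slides an edit-distance window (edlib) over every genome offset
instead of seeding and banded alignment; the literal SAM filter re-applies
the textual command semantics (keep the header and proper pairs, drop lines
containing the multi-hit tag) to raw SAM lines; the brute-force counter
checks every fragment against every locus linearly.  They exist so the fast
implementations can be validated against slow, obviously-correct ones.
"""

from __future__ import annotations

from typing import Sequence

import edlib

from .io_formats import GenomeSequence, GenomicInterval, reverse_complement


def exhaustive_scan(
    genome: GenomeSequence,
    query_sequence: str,
    threshold: float = 94.0,
) -> list[tuple[GenomicInterval, float]]:
    """Sliding-window scan at every offset on both strands.

    At each offset the query is globally aligned (unit-cost edit distance)
    to the same-length window; identity is (L - distance) / L.  Runs of
    above-threshold offsets are reduced to their best offset, then a greedy
    non-overlap pass keeps the best-identity hits.  Quadratic and simple —
    an oracle, not a scanner.
    """
    L = len(query_sequence)
    contig = genome.residues
    max_d = int(L * (1 - threshold / 100.0)) + 2  # early-abort bound
    per_offset: list[tuple[int, str, float]] = []
    for strand, q in (("+", query_sequence), ("-", reverse_complement(query_sequence))):
        for p in range(len(contig) - L + 1):
            res = edlib.align(q, contig[p : p + L], mode="NW", task="distance", k=max_d)
            d = res["editDistance"]
            if d < 0:
                continue
            identity = 100.0 * (L - d) / L
            if identity >= threshold:
                per_offset.append((p, strand, identity))
    # keep local maxima: greedy by identity, suppressing overlapping offsets
    per_offset.sort(key=lambda t: (-t[2], t[0], t[1]))
    hits: list[tuple[GenomicInterval, float]] = []
    for p, strand, identity in per_offset:
        iv = GenomicInterval(genome.name, p, p + L, strand)
        if all(not iv.overlaps(h[0]) for h in hits):
            hits.append((iv, identity))
    hits.sort(key=lambda h: h[0].start)
    return hits


def literal_sam_filter(sam_text: str, tag: str = "ZS") -> list[str]:
    """The quoted filter pipeline applied literally to SAM text.

    Equivalent to ``samtools view -f 0x2 | awk 'header || $0 !~ /ZS:/'``
    plus fragment-level consistency: if any line of a read pair carries the
    tag, all lines with that read name are dropped.  Returns kept alignment
    lines (header excluded).
    """
    body = [ln for ln in sam_text.splitlines() if ln and not ln.startswith("@")]
    proper = []
    tagged_names: set[str] = set()
    for ln in body:
        fields = ln.split("\t")
        flag = int(fields[1])
        if not flag & 0x2:
            continue
        if flag & 0x100 or flag & 0x800:
            continue
        proper.append(ln)
        if f"{tag}:" in ln:
            tagged_names.add(fields[0])
    return [ln for ln in proper if ln.split("\t", 1)[0] not in tagged_names]


def brute_force_fragment_counts(
    fragments: Sequence[tuple[str, int, int, str]],
    loci: Sequence[tuple[str, str, int, int, str]],
    strandedness: str = "reverse",
) -> dict[str, int]:
    """Linear-scan fragment counting.

    ``fragments``: (chrom, start, end, transcript_strand) per fragment,
    where transcript_strand is the library-inferred sense strand ('.' if
    unstranded).  ``loci``: (id, chrom, start, end, strand).  A fragment
    counts for a locus when intervals overlap by >= 1 nt and, for stranded
    data, strands agree; fragments overlapping two loci count for none.
    """
    counts = {locus_id: 0 for locus_id, *_ in loci}
    for chrom, start, end, tstrand in fragments:
        touching = [
            (locus_id, lstrand)
            for locus_id, lchrom, lstart, lend, lstrand in loci
            if lchrom == chrom and start < lend and lstart < end
        ]
        if len(touching) != 1:
            continue
        locus_id, lstrand = touching[0]
        if strandedness != "unstranded" and tstrand in "+-" and tstrand != lstrand:
            continue
        counts[locus_id] += 1
    return counts
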