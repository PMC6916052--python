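"""Genomic context for element hits.

Each hit is placed relative to gene models (which gene, sense or antisense,
intronic or exonic or intergenic) and an LTR catalog, reproducing the kind
of summary table used to report RcRE-containing gene regions.  Hits with
identical sequences are collapsed into unique element groups, since solo
direct-repeat LTRs can carry byte-identical elements in one region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .element_scan import ElementHit
from .io_formats import AnnotationSet, Feature

#: minimum fraction of the hit covered by a gene span for gene assignment
GENE_OVERLAP_FRACTION = 0.5
#: minimum reciprocal overlap for an LTR-catalog match
LTR_RECIPROCAL_OVERLAP = 0.8


@dataclass(frozen=True)
class GeneContext:
    """Where a hit sits relative to gene models and the LTR catalog."""

    hit: ElementHit
    gene_id: str | None
    gene_name: str | None
    orientation: str  # sense | antisense | not_applicable
    context: str  # intronic | exonic | intergenic
    ltr_id: str | None
    secondary: tuple["GeneContext", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.orientation == "not_applicable"):
            raise ValueError("orientation is not_applicable iff no gene is assigned")


@dataclass(frozen=True)
class UniqueElementGroup:
    """Hits sharing one exact element sequence, and the regions they occupy."""

    representative_sequence: str
    member_hits: tuple[ElementHit, ...]
    n_regions: int


def _gene_context_for(hit: ElementHit, gene: Feature, genes: AnnotationSet,
                      ltr_id: str | None) -> GeneContext:
    orientation = "sense" if hit.strand == gene.interval.strand else "antisense"
    exons = [
        f for f in genes.query(hit.interval, kind="exon")
        if f.attributes.get("gene_id") == gene.id
    ]
    context = "exonic" if exons else "intronic"
    return GeneContext(hit, gene.id, gene.attributes.get("gene_name"),
                       orientation, context, ltr_id)


def _best_ltr(hit: ElementHit, ltr_catalog: AnnotationSet) -> str | None:
    best_id, best_ov = None, 0
    for ltr in ltr_catalog.query(hit.interval, kind="LTR"):
        ov = hit.interval.overlap_length(ltr.interval)
        if (ov >= LTR_RECIPROCAL_OVERLAP * len(hit.interval)
                and ov >= LTR_RECIPROCAL_OVERLAP * len(ltr.interval)
                and ov > best_ov):
            best_id, best_ov = ltr.id, ov
    return best_id


def annotate_hit(hit: ElementHit, genes: AnnotationSet,
                 ltr_catalog: AnnotationSet | None = None) -> GeneContext:
    """Assign a hit to a gene, orientation and intron/exon context.

    A gene qualifies when its full span covers at least half of the hit.
    When several qualify, the one with the largest overlap is primary and the
    others are kept as secondary contexts.  Orientation is sense iff the hit
    strand equals the gene strand; context is exonic if the hit touches any
    annotated exon of the assigned gene, intronic otherwise; hits outside
    every gene are intergenic.
    """
    overlapping = [
        g for g in genes.query(hit.interval, kind="gene")
        if hit.interval.overlap_length(g.interval) >= GENE_OVERLAP_FRACTION * len(hit.interval)
    ]
    ltr_id = _best_ltr(hit, ltr_catalog) if ltr_catalog is not None else None
    if not overlapping:
        return GeneContext(hit, None, None, "not_applicable", "intergenic", ltr_id)
    overlapping.sort(key=lambda g: (-hit.interval.overlap_length(g.interval), g.id))
    primary, *rest = overlapping
    secondary = tuple(_gene_context_for(hit, g, genes, ltr_id) for g in rest)
    ctx = _gene_context_for(hit, primary, genes, ltr_id)
    if secondary:
        ctx = GeneContext(ctx.hit, ctx.gene_id, ctx.gene_name, ctx.orientation,
                          ctx.context, ctx.ltr_id, secondary)
    return ctx


def collapse_unique(hits: Sequence[ElementHit],
                    contexts: Sequence[GeneContext]) -> list[UniqueElementGroup]:
    """Collapse hits with byte-identical sequences into unique element groups.

    ``n_regions`` counts the distinct gene regions a group's members occupy;
    a region holding two identical direct-repeat copies therefore counts
    once.  Groups are ordered by first occurrence.
    """
    if len(hits) != len(contexts):
        raise ValueError("hits and contexts must align one-to-one")
    order: list[str] = []
    members: dict[str, list[ElementHit]] = {}
    regions: dict[str, set[str]] = {}
    for hit, ctx in zip(hits, contexts):
        seq = hit.hit_sequence
        if seq not in members:
            order.append(seq)
            members[seq] = []
            regions[seq] = set()
        members[seq].append(hit)
        region = ctx.gene_id if ctx.gene_id is not None else f"intergenic:{hit.interval.chrom}:{hit.interval.start}"
        regions[seq].add(region)
    return [
        UniqueElementGroup(seq, tuple(members[seq]), len(regions[seq]))
        for seq in order
    ]


def context_table(contexts: Sequence[GeneContext]) -> pd.DataFrame:
    """Summary table of annotated hits: gene, name, location, orientation, LTR.

    Locations are 1-based inclusive report strings with thousands separators.
    """
    rows = []
    for ctx in contexts:
        rows.append(
            {
                "gene_id": ctx.gene_id or "",
                "gene_name": ctx.gene_name or "",
                "location": ctx.hit.interval.as_report_string(),
                "strand": ctx.hit.strand,
                "orientation": ctx.orientation,
                "context": ctx.context,
                "identity_pct": round(ctx.hit.identity_pct, 1),
                "ltr_id": ctx.ltr_id or "",
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "location", "strand",
                                       "orientation", "context", "identity_pct", "ltr_id"])
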