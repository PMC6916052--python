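"""Readers, writers and in-memory containers for the genomic formats the
pipeline consumes.

All coordinates are 0-based half-open internally.  GTF I/O converts between
the 1-based inclusive convention at the file boundary; BED and SAM share the
internal convention.  Report strings use the 1-based inclusive,
thousands-separated style common in summary tables
(``chr1:1,410,022-1,410,454``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam
from intervaltree import IntervalTree


class FormatError(ValueError):
    """A file did not conform to its declared format."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_DNA_RE = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome or contig; residues over {A,C,G,T,N}, upper case."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GenomeSequence requires a non-empty name")
        if not _DNA_RE.match(self.residues):
            raise ValueError(
                f"sequence {self.name!r} contains characters outside ACGTN"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval with strand in {'+', '-', '.'}."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval requires a chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def as_report_string(self) -> str:
        """1-based inclusive with thousands separators, e.g. chr1:1,234-5,678."""
        return f"{self.chrom}:{self.start + 1:,}-{self.end:,}"


@dataclass(frozen=True)
class Feature:
    """An annotated feature: a gene, exon, proviral locus, or LTR."""

    interval: GenomicInterval
    kind: str  # gene | exon | locus | LTR
    id: str
    attributes: Mapping[str, str] = field(default_factory=dict)


class AnnotationSet:
    """A collection of features with a per-chromosome interval-overlap index.

    Feature ids must be unique within a kind.  Overlap queries are backed by
    an interval tree and return exactly the features whose intervals overlap
    the query (verified against a linear scan in the test suite).
    """

    def __init__(self, features: Iterable[Feature] = ()):
        self.features: list[Feature] = []
        self._trees: dict[str, IntervalTree] = {}
        self._by_kind_id: dict[tuple[str, str], Feature] = {}
        for f in features:
            self.add(f)

    def add(self, feature: Feature) -> None:
        key = (feature.kind, feature.id)
        if key in self._by_kind_id:
            raise ValueError(f"duplicate feature id {feature.id!r} for kind {feature.kind!r}")
        self._by_kind_id[key] = feature
        self.features.append(feature)
        tree = self._trees.setdefault(feature.interval.chrom, IntervalTree())
        tree.addi(feature.interval.start, feature.interval.end, feature)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def query(self, interval: GenomicInterval, kind: str | None = None) -> list[Feature]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(interval.start, interval.end)]
        if kind is not None:
            hits = [f for f in hits if f.kind == kind]
        hits.sort(key=lambda f: (f.interval.start, f.interval.end, f.id))
        return hits

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class AlignmentRecord:
    """A minimal stranded paired-end alignment record.

    Only the flag bits and tags the unique-mapping filter interprets are
    modelled; everything else in the SAM line is opaque.
    """

    qname: str
    interval: GenomicInterval
    paired: bool = False
    proper_pair: bool = False
    secondary: bool = False
    supplementary: bool = False
    reverse_strand: bool = False
    first_in_pair: bool = False
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.proper_pair and not self.paired:
            raise ValueError("proper_pair implies paired")


class CountMatrix:
    """Loci x samples fragment counts plus per-sample metadata.

    ``counts`` is a non-negative integer DataFrame indexed by locus id with
    sample ids as columns; ``sample_meta`` is indexed by sample id with at
    least ``condition`` and ``compartment`` columns.
    """

    def __init__(self, counts: pd.DataFrame, sample_meta: pd.DataFrame):
        counts = counts.astype("int64")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not counts.columns.equals(sample_meta.index):
            missing = set(counts.columns).symmetric_difference(sample_meta.index)
            raise ValueError(f"sample ids inconsistent between counts and metadata: {missing}")
        self.counts = counts
        self.sample_meta = sample_meta

    @property
    def locus_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[sample_ids], self.sample_meta.loc[sample_ids])

    def samples_where(self, **criteria: str) -> list[str]:
        mask = pd.Series(True, index=self.sample_meta.index)
        for col, val in criteria.items():
            mask &= self.sample_meta[col] == val
        return list(self.sample_meta.index[mask])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a multi-record FASTA file.

    Residues are upper-cased and U is mapped to T, so RNA input is accepted.
    """
    records: list[GenomeSequence] = []
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            seq = "".join(chunks).upper().replace("U", "T")
            records.append(GenomeSequence(name, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before first header at line {lineno}")
                chunks.append(line)
    flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, sequences: Iterable[GenomeSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.name}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return {k: v for k, v in _GTF_ATTR_RE.findall(text)}


def read_gtf(path: str | Path) -> AnnotationSet:
    """Read a 9-column GTF file into an :class:`AnnotationSet`.

    GTF's 1-based inclusive coordinates are converted to 0-based half-open.
    The feature id is taken from the ``gene_id`` attribute (``locus_id`` or
    ``ltr_id`` override it for those kinds when present).
    """
    out = AnnotationSet()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            chrom, _source, kind, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start1 > end1 or start1 < 1:
                raise FormatError(f"{path}:{lineno}: invalid coordinate range {start1}-{end1}")
            attrs = _parse_gtf_attributes(attr_s)
            if "gene_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: missing required attribute gene_id")
            fid = attrs.get("locus_id") or attrs.get("ltr_id") or attrs["gene_id"]
            if kind == "exon":
                # exon ids must be unique per kind; derive one if absent
                fid = attrs.get("exon_id", f"{attrs['gene_id']}:exon:{lineno}")
            interval = GenomicInterval(chrom, start1 - 1, end1, strand if strand in "+-" else ".")
            out.add(Feature(interval, kind, fid, attrs))
    return out


def write_gtf(path: str | Path, annotations: AnnotationSet, source: str = "rcre_kit") -> None:
    """Serialize an AnnotationSet as GTF, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for f in annotations:
            attrs = dict(f.attributes)
            attrs.setdefault("gene_id", f.id)
            attr_s = " ".join(f'{k} "{v}";' for k, v in attrs.items())
            iv = f.interval
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.chrom}\t{source}\t{f.kind}\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, kind: str = "LTR") -> AnnotationSet:
    """Read a BED6 file; the name column becomes the feature id."""
    out = AnnotationSet()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs at least 4 columns")
            chrom, start_s, end_s, name = cols[:4]
            strand = cols[5] if len(cols) >= 6 and cols[5] in "+-" else "."
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            out.add(Feature(GenomicInterval(chrom, start, end, strand), kind, name))
    return out


def write_bed(path: str | Path, rows: Iterable[tuple[GenomicInterval, str, float]]) -> None:
    """Write BED6 rows given (interval, name, score) tuples."""
    with open(path, "w") as fh:
        for iv, name, score in rows:
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n")


# ---------------------------------------------------------------------------
# Annotation merge / sort
# ---------------------------------------------------------------------------

def chromosome_sort_key(chrom: str) -> tuple[int, float, str]:
    """Order chromosomes numerically where possible, else lexicographically.

    'chr' prefixes are stripped; purely numeric names sort before non-numeric
    ones (chr1, chr2, ..., chr22, chrX, chrY, chrM).
    """
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0.0, name)


def merge_annotations(host: AnnotationSet, custom: AnnotationSet) -> AnnotationSet:
    """Union two annotation sets, ordered by chromosome then start position.

    This mirrors the merge-and-sort step used to splice a custom proviral
    locus GTF into a host gene-model GTF: concatenate, sort on chromosome
    (natural-numeric), then on start coordinate; the sort is stable.
    """
    for f in custom:
        if any((f.kind, f.id) == (g.kind, g.id) for g in host):
            raise ValueError(f"duplicate feature id across sets: {f.kind}/{f.id}")
    merged = list(host) + list(custom)
    merged.sort(key=lambda f: (chromosome_sort_key(f.interval.chrom), f.interval.start))
    return AnnotationSet(merged)


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

def read_alignments(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream alignment records from a SAM (or BAM) file with a header.

    Coordinates come back 0-based half-open; unmapped records are skipped.
    Optional tags are kept as strings keyed by tag name.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    try:
        af = pysam.AlignmentFile(str(path), mode, check_sq=False)
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot open alignment file: {exc}") from None
    with af:
        if not af.header.references:
            raise FormatError(f"{path}: missing @SQ header lines")
        for rec in af:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            end = rec.reference_end if rec.reference_end is not None else rec.reference_start + 1
            yield AlignmentRecord(
                qname=rec.query_name,
                interval=GenomicInterval(
                    rec.reference_name,
                    rec.reference_start,
                    max(end, rec.reference_start + 1),
                    "-" if rec.is_reverse else "+",
                ),
                paired=rec.is_paired,
                proper_pair=rec.is_proper_pair,
                secondary=rec.is_secondary,
                supplementary=rec.is_supplementary,
                reverse_strand=rec.is_reverse,
                first_in_pair=rec.is_read1,
                tags={tag: str(val) for tag, val in rec.get_tags()},
            )


# ---------------------------------------------------------------------------
# bedGraph and TSV tables
# ---------------------------------------------------------------------------

def write_bedgraph(path: str | Path, bins: Mapping[str, "list[float]"], bin_width: int) -> None:
    """Write fixed-width binned values as bedGraph, merging equal-value runs."""
    with open(path, "w") as fh:
        for chrom in sorted(bins, key=chromosome_sort_key):
            values = bins[chrom]
            i = 0
            while i < len(values):
                j = i
                while j + 1 < len(values) and values[j + 1] == values[i]:
                    j += 1
                fh.write(f"{chrom}\t{i * bin_width}\t{(j + 1) * bin_width}\t{values[i]:g}\n")
                i = j + 1


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_count_matrix(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta.loc[counts.columns])
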