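"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions the pipeline was built for: a
genome carrying implanted degenerate copies of a ~433-nt element at
controlled identities and strands, gene models and an LTR catalog around
them, dUTP-stranded paired-end fragments over repetitive proviral loci
(shared segments marked with a multi-hit tag, as an aligner would), and
negative-binomial count matrices with known size factors and per-locus fold
changes.  Every generator is a pure function of its spec and seed; truth
records carry everything downstream tests need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .element_scan import QueryElement, global_align
from .io_formats import (
    AnnotationSet,
    CountMatrix,
    Feature,
    GenomeSequence,
    GenomicInterval,
    reverse_complement,
)
from .overlaps_stats import DETable

BASES = np.array(list("ACGT"))
DEMO_SEED = 42


# ---------------------------------------------------------------------------
# Genome and implants
# ---------------------------------------------------------------------------

def make_genome(length: int, gc: float = 0.41, seed: int = DEMO_SEED,
                name: str = "chrS") -> GenomeSequence:
    """A random genome with the requested GC content (human-like 0.41 default)."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    residues = "".join(rng.choice(BASES, size=length, p=p))
    return GenomeSequence(name, residues)


def make_query(length: int = 433, gc: float = 0.5, seed: int = DEMO_SEED,
               id: str = "prototype_element") -> QueryElement:
    """A random prototype element, by default RcRE-sized (433 nt)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return QueryElement(id, "".join(rng.choice(BASES, size=length, p=p)))


@dataclass(frozen=True)
class ImplantSpec:
    """A degenerate copy to implant: identity target, strand, location.

    ``indel_fraction`` is the fraction of edits realized as 1-2 nt indels
    rather than substitutions (0 by default, so realized identity equals the
    target up to rounding).
    """

    target_identity: float
    strand: str = "+"
    location: int | None = None  # None = random placement
    indel_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (50.0 < self.target_identity <= 100.0):
            raise ValueError("target identity must be in (50, 100]")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise ValueError("indel_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ImplantTruth:
    interval: GenomicInterval
    strand: str
    identity_pct: float  # realized, from global alignment to the query
    sequence: str  # query-oriented implanted sequence


def _mutate(query: str, spec: ImplantSpec, rng: np.random.Generator) -> str:
    """Introduce the number of edits implied by the identity target."""
    L = len(query)
    n_edits = int(round(L * (1 - spec.target_identity / 100.0)))
    if n_edits == 0:
        return query
    n_indels = int(round(spec.indel_fraction * n_edits))
    n_subs = n_edits - n_indels
    positions = rng.choice(L, size=n_edits, replace=False)
    sub_pos = set(positions[:n_subs].tolist())
    indel_pos = sorted(positions[n_subs:].tolist(), reverse=True)
    seq = list(query)
    for i in sorted(sub_pos):
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(3)]
    for i in indel_pos:  # right-to-left so earlier positions stay valid
        size = int(rng.integers(1, 3))
        if rng.random() < 0.5:
            del seq[i : i + size]
        else:
            ins = "".join(rng.choice(BASES, size=size))
            seq.insert(i, ins)
    return "".join(seq)


def implant(
    genome: GenomeSequence,
    query: QueryElement,
    spec: ImplantSpec,
    seed: int = DEMO_SEED,
    occupied: Sequence[GenomicInterval] = (),
) -> tuple[GenomeSequence, ImplantTruth]:
    """Replace a stretch of the genome with a mutated copy of the query.

    The truth record holds the exact interval, strand, the query-oriented
    implanted sequence, and the realized identity computed by global
    alignment (within +-0.5 points of the target for substitution-only
    implants).  Overlap with a previously implanted interval is an error.
    """
    rng = np.random.default_rng(seed)
    mutated = _mutate(query.sequence, spec, rng)
    L = len(mutated)
    if L > len(genome):
        raise ValueError("implant does not fit in the genome")
    if spec.location is None:
        for _ in range(1000):
            loc = int(rng.integers(0, len(genome) - L + 1))
            cand = GenomicInterval(genome.name, loc, loc + L)
            if all(not cand.overlaps(o) for o in occupied):
                break
        else:
            raise ValueError("could not place implant without overlap")
    else:
        loc = spec.location
        if loc + L > len(genome):
            raise ValueError("implant does not fit at the requested location")
        cand = GenomicInterval(genome.name, loc, loc + L)
        if any(cand.overlaps(o) for o in occupied):
            raise ValueError(f"implant at {loc} overlaps a previous implant")
    inserted = mutated if spec.strand == "+" else reverse_complement(mutated)
    residues = genome.residues[:loc] + inserted + genome.residues[loc + L:]
    realized = global_align(query.sequence, mutated).identity_pct
    truth = ImplantTruth(
        GenomicInterval(genome.name, loc, loc + L, spec.strand),
        spec.strand, realized, mutated,
    )
    return GenomeSequence(genome.name, residues), truth


def implant_many(
    genome: GenomeSequence,
    query: QueryElement,
    specs: Sequence[ImplantSpec],
    seed: int = DEMO_SEED,
) -> tuple[GenomeSequence, list[ImplantTruth]]:
    """Implant several copies, guaranteeing (and checking) non-overlap."""
    truths: list[ImplantTruth] = []
    for i, spec in enumerate(specs):
        genome, truth = implant(
            genome, query, spec, seed=seed + 7919 * (i + 1),
            occupied=[t.interval for t in truths],
        )
        truths.append(truth)
    return genome, truths


# ---------------------------------------------------------------------------
# Gene models and LTR catalogs
# ---------------------------------------------------------------------------

def make_gene_models(
    genes: Sequence[tuple[str, str, int, int, str]],
    exons: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    names: Mapping[str, str] | None = None,
) -> AnnotationSet:
    """Build gene/exon annotations from (gene_id, chrom, start, end, strand)
    tuples plus optional per-gene exon intervals and display names."""
    out = AnnotationSet()
    exons = exons or {}
    names = names or {}
    for gene_id, chrom, start, end, strand in genes:
        attrs = {"gene_id": gene_id}
        if gene_id in names:
            attrs["gene_name"] = names[gene_id]
        out.add(Feature(GenomicInterval(chrom, start, end, strand), "gene", gene_id, attrs))
        for k, (es, ee) in enumerate(exons.get(gene_id, ()), 1):
            out.add(Feature(GenomicInterval(chrom, es, ee, strand), "exon",
                            f"{gene_id}:exon:{k}", {"gene_id": gene_id}))
    return out


def make_ltr_catalog(ltrs: Sequence[tuple[str, str, int, int, str]]) -> AnnotationSet:
    """Build an LTR catalog from (ltr_id, chrom, start, end, strand) tuples."""
    out = AnnotationSet()
    for ltr_id, chrom, start, end, strand in ltrs:
        out.add(Feature(GenomicInterval(chrom, start, end, strand), "LTR", ltr_id))
    return out


# ---------------------------------------------------------------------------
# Stranded paired-end alignments over repetitive loci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimLocus:
    """A proviral locus with a unique segment and an optional shared segment.

    Fragments simulated from the shared segment (sequence duplicated
    verbatim at another locus) are emitted with the multi-hit tag, the way
    an aligner marks reads with a scored secondary hit; unique-segment
    fragments carry no tag.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    n_unique_fragments: int = 0
    n_shared_fragments: int = 0
    shared_span: tuple[int, int] | None = None  # defaults to the second half


@dataclass(frozen=True)
class SimAlignmentSpec:
    loci: Sequence[SimLocus]
    strandedness: str = "reverse"
    read_length: int = 75
    fragment_min: int = 150
    fragment_max: int = 200
    multihit_tag: str = "ZS"
    n_improper: int = 0  # extra non-proper-pair records
    n_secondary: int = 0  # extra secondary records
    chrom_lengths: Mapping[str, int] | None = None


def _sam_flags(locus_strand: str, strandedness: str) -> tuple[int, int]:
    """FLAG values for (read1, read2) of a proper pair from a stranded library."""
    r1_reverse = (locus_strand == "+") == (strandedness == "reverse")
    if strandedness == "unstranded":
        r1_reverse = locus_strand == "+"  # arbitrary fixed orientation
    if r1_reverse:
        return 0x1 | 0x2 | 0x10 | 0x40, 0x1 | 0x2 | 0x20 | 0x80  # 83, 163
    return 0x1 | 0x2 | 0x20 | 0x40, 0x1 | 0x2 | 0x10 | 0x80  # 99, 147


def simulate_alignments(spec: SimAlignmentSpec, seed: int = DEMO_SEED) -> tuple[str, dict[str, int]]:
    """Emit SAM text for fragments drawn from the spec's loci, plus truth.

    Truth maps locus id to the number of unique-segment fragments — exactly
    what unique-filtered counting should recover.  dUTP orientation is
    honored: for a 'reverse' library the first-in-pair read is antisense to
    the locus.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths: dict[str, int] = dict(spec.chrom_lengths or {})
    for locus in spec.loci:
        chrom_lengths[locus.chrom] = max(chrom_lengths.get(locus.chrom, 0), locus.end + 1000)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{c}\tLN:{n}" for c, n in sorted(chrom_lengths.items())]

    truth: dict[str, int] = {}
    frag_no = 0

    def emit_pair(locus: SimLocus, span: tuple[int, int], tag: str | None) -> None:
        nonlocal frag_no
        frag_no += 1
        lo, hi = span
        flen = int(rng.integers(spec.fragment_min, spec.fragment_max + 1))
        if flen > hi - lo:
            raise ValueError(f"fragment length {flen} exceeds segment of locus {locus.id}")
        start = int(rng.integers(lo, hi - flen + 1))
        end = start + flen
        f1, f2 = _sam_flags(locus.strand, spec.strandedness)
        left_is_r1 = not bool(f1 & 0x10)  # forward read1 sits at the left end
        qname = f"frag{frag_no:06d}"
        opt = f"\t{spec.multihit_tag}:i:{int(rng.integers(20, 60))}" if tag else ""
        rl = spec.read_length
        left_pos, right_pos = start + 1, end - rl + 1  # SAM 1-based
        recs = [
            (f1, left_pos if left_is_r1 else right_pos, flen if left_is_r1 else -flen),
            (f2, right_pos if left_is_r1 else left_pos, -flen if left_is_r1 else flen),
        ]
        for flag, pos, tlen in recs:
            lines.append(
                f"{qname}\t{flag}\t{locus.chrom}\t{pos}\t60\t{rl}M\t=\t"
                f"{right_pos if pos == left_pos else left_pos}\t{tlen}\t*\t*{opt}"
            )

    for locus in spec.loci:
        truth[locus.id] = locus.n_unique_fragments
        shared = locus.shared_span or ((locus.start + locus.end) // 2, locus.end)
        if locus.n_shared_fragments == 0 and locus.shared_span is None:
            unique = (locus.start, locus.end)
        else:
            unique = (locus.start, shared[0])
        for _ in range(locus.n_unique_fragments):
            emit_pair(locus, unique, None)
        for _ in range(locus.n_shared_fragments):
            emit_pair(locus, shared, spec.multihit_tag)

    some_chrom = next(iter(sorted(chrom_lengths)))
    for i in range(spec.n_improper):
        lines.append(f"junk_unpaired{i}\t0\t{some_chrom}\t{100 + i}\t60\t{spec.read_length}M\t*\t0\t0\t*\t*")
    for i in range(spec.n_secondary):
        lines.append(
            f"junk_secondary{i}\t{0x1 | 0x2 | 0x100 | 0x40}\t{some_chrom}\t{200 + i}\t0\t{spec.read_length}M\t=\t{200 + i}\t0\t*\t*"
        )
    return "\n".join(lines) + "\n", truth


def loci_annotation(loci: Sequence[SimLocus]) -> AnnotationSet:
    """The AnnotationSet (kind='locus') matching a SimAlignmentSpec."""
    out = AnnotationSet()
    for locus in loci:
        out.add(Feature(GenomicInterval(locus.chrom, locus.start, locus.end, locus.strand),
                        "locus", locus.id, {"gene_id": locus.id}))
    return out


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimCountSpec:
    """NB count-matrix spec with known size factors and fold changes.

    Counts for sample j, locus i are NB with mean
    baseline_i * 2^(log2_fc_i * [condition_j == treatment]) * size_factor_j
    and the given dispersion (variance mu + dispersion * mu^2).
    """

    n_loci: int = 20
    n_replicates: int = 3
    baseline_mean: float | Sequence[float] = 500.0
    dispersion: float = 0.05
    size_factors: Sequence[float] | None = None  # per sample, EV group first
    log2_fc: float | Sequence[float] = 0.0
    treatment: str = "Rev"
    reference: str = "EV"
    compartment: str = "cytoplasmic"


@dataclass(frozen=True)
class SimCountTruth:
    baseline: np.ndarray
    log2_fc: np.ndarray
    size_factors: np.ndarray
    dispersion: float


def simulate_counts(spec: SimCountSpec, seed: int = DEMO_SEED) -> tuple[CountMatrix, SimCountTruth]:
    rng = np.random.default_rng(seed)
    n = spec.n_loci
    baseline = np.broadcast_to(np.asarray(spec.baseline_mean, dtype=float), (n,)).copy()
    lfc = np.broadcast_to(np.asarray(spec.log2_fc, dtype=float), (n,)).copy()
    conditions = [spec.reference] * spec.n_replicates + [spec.treatment] * spec.n_replicates
    n_samples = len(conditions)
    sf = np.ones(n_samples) if spec.size_factors is None else np.asarray(spec.size_factors, float)
    if sf.size != n_samples:
        raise ValueError("size_factors must have one entry per sample")
    sample_ids = [
        f"{cond}_{spec.compartment}_r{i % spec.n_replicates + 1}"
        for i, cond in enumerate(conditions)
    ]
    treated = np.array([c == spec.treatment for c in conditions], dtype=float)
    mu = baseline[:, None] * (2.0 ** (lfc[:, None] * treated[None, :])) * sf[None, :]
    if spec.dispersion > 0:
        lam = rng.gamma(shape=1.0 / spec.dispersion, scale=mu * spec.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    frame = pd.DataFrame(counts, index=[f"locus{i + 1}" for i in range(n)], columns=sample_ids)
    meta = pd.DataFrame(
        {"condition": conditions, "compartment": [spec.compartment] * n_samples},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(frame, meta), SimCountTruth(baseline, lfc, sf, spec.dispersion)


# ---------------------------------------------------------------------------
# DE tables and reporter measurements
# ---------------------------------------------------------------------------

def simulate_de_table(n_null: int = 1000, n_true: int = 50,
                      seed: int = DEMO_SEED) -> tuple[DETable, frozenset[str]]:
    """A DE table of uniform-null p-values plus strongly significant genes.

    Returns the table and the set of true-positive gene ids.
    """
    rng = np.random.default_rng(seed)
    null_ids = [f"NULL{i + 1}" for i in range(n_null)]
    true_ids = [f"TRUE{i + 1}" for i in range(n_true)]
    p = np.concatenate([rng.uniform(0, 1, n_null), rng.uniform(0, 1e-7, n_true)])
    table = DETable(pd.DataFrame({"gene_id": null_ids + true_ids, "p_value": p}))
    return table, frozenset(true_ids)


def make_reporter_table(
    activities: Mapping[str, float],
    reference_pair: str = "Rec/prRcRE",
    reference_p24: float = 6.4,
    seed: int = DEMO_SEED,
    seap_cv: float = 0.2,
) -> pd.DataFrame:
    """Reporter measurements with known relative activities.

    SEAP varies log-normally around 1e5 RLU (transfection-efficiency noise);
    p24 is proportional to activity x SEAP so that SEAP normalization
    recovers the truth exactly.  The reference pair has activity 1 and raw
    p24 ``reference_p24`` ng/ml at nominal SEAP.
    """
    if reference_pair not in activities:
        raise ValueError("activities must include the reference pair")
    rng = np.random.default_rng(seed)
    rows = []
    for i, (pair, act) in enumerate(activities.items()):
        seap = 1e5 * rng.lognormal(0, seap_cv) if pair != reference_pair else 1e5
        rows.append(
            {"sample_id": f"tx{i + 1}", "pair": pair,
             "p24": reference_p24 * act * seap / 1e5, "seap": seap}
        )
    return pd.DataFrame(rows)
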