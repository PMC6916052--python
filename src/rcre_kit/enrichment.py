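"""Normalization, per-locus differential tests and reporter-assay ratios.

Count matrices are depth-normalized with median-of-ratios size factors.
Per-locus differences between a condition and the empty-vector (EV)
reference, within one RNA compartment (total or cytoplasmic), are tested
with a simplified negative-binomial Wald test: method-of-moments dispersion,
a 0.5 pseudo-count in the fold change, a delta-method standard error and a
two-sided normal reference.  This deliberately omits dispersion shrinkage
and outlier handling; it is validated by parameter recovery and null
calibration rather than numerical identity to any particular DE package.

Reporter measurements (p24 antigen normalized by co-transfected SEAP) are
expressed relative to a reference export-factor/element pair whose activity
is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix
from .overlaps_stats import bh_adjust

_LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors.

    The per-locus reference is the geometric mean across samples, computed
    over loci with no zero count; each sample's factor is the median over
    those loci of count / reference.  For two samples where one is a global
    c-fold scaling of the other, the factors are [1/sqrt(c), sqrt(c)].
    """
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    x = frame.to_numpy(dtype=float)
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no locus has positive counts in every sample; supply deeper data "
            "or construct a pseudo-reference over nonzero loci"
        )
    logs = np.log(x[all_positive])
    log_ref = logs.mean(axis=1, keepdims=True)  # per-locus geometric mean
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(factors, index=frame.columns, name="size_factor")


def normalized_counts(counts: CountMatrix | pd.DataFrame,
                      factors: pd.Series | None = None) -> pd.DataFrame:
    frame = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(frame)
    return frame / factors


@dataclass(frozen=True)
class DEResult:
    locus_id: str
    log2_fc: float
    se: float
    wald_p: float
    q: float
    fold_change: float
    base_mean: float


def _moment_dispersion(norm: np.ndarray, groups: Sequence[np.ndarray]) -> np.ndarray:
    """Per-locus method-of-moments NB dispersion, pooled across groups.

    Within each group, alpha = (s^2 - m) / m^2 from the group sample mean
    and variance of normalized counts; the per-locus estimate averages the
    groups and is floored at DISPERSION_FLOOR.
    """
    ests = []
    for idx in groups:
        sub = norm[:, idx]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        ests.append(a)
    alpha = np.mean(ests, axis=0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    contrast: tuple[str, str] = ("Rev", "EV"),
    compartment: str | None = None,
    dispersion: Literal["per-locus", "pooled"] = "pooled",
) -> list[DEResult]:
    """Simplified NB Wald test of one condition against a reference.

    Counts are normalized by ``factors`` (median-of-ratios by default);
    group means are compared as log2((m_t + 0.5) / (m_r + 0.5)) with a
    delta-method standard error from the NB variance mu + alpha mu^2 and a
    two-sided normal Wald p-value, BH-adjusted across loci.  With
    ``dispersion='pooled'`` (default) the per-locus method-of-moments
    estimates are averaged across all loci before use, which stabilises the
    variance at small replicate numbers; 'per-locus' uses each locus's own
    estimate.  Loci with zero counts in both groups are omitted.
    """
    treatment, reference = contrast
    meta = counts.sample_meta
    if compartment is not None:
        if "compartment" not in meta.columns:
            raise ValueError("sample metadata lacks a compartment column")
        keep = meta.index[meta["compartment"] == compartment]
        if keep.empty:
            raise ValueError(f"no samples in compartment {compartment!r}: a group has zero replicates")
        counts = counts.subset_samples(list(keep))
        meta = counts.sample_meta
    if factors is None:
        factors = size_factors(counts)
    factors = factors.loc[counts.sample_ids]

    cols = np.asarray(counts.sample_ids)
    t_idx = np.flatnonzero(meta.loc[cols, "condition"].to_numpy() == treatment)
    r_idx = np.flatnonzero(meta.loc[cols, "condition"].to_numpy() == reference)
    if t_idx.size == 0 or r_idx.size == 0:
        raise ValueError(f"contrast {treatment!r} vs {reference!r}: a group has no replicates")

    norm = (counts.counts.to_numpy(dtype=float) / factors.to_numpy())
    locus_ids = np.asarray(counts.locus_ids)
    nonzero = norm[:, np.concatenate([t_idx, r_idx])].sum(axis=1) > 0
    norm = norm[nonzero]
    locus_ids = locus_ids[nonzero]
    if norm.shape[0] == 0:
        return []

    alpha = _moment_dispersion(norm, [t_idx, r_idx])
    if dispersion == "pooled":
        alpha = np.full_like(alpha, max(float(alpha.mean()), DISPERSION_FLOOR))

    m_t = norm[:, t_idx].mean(axis=1)
    m_r = norm[:, r_idx].mean(axis=1)
    log2_fc = np.log2((m_t + 0.5) / (m_r + 0.5))
    var_t = (m_t + alpha * m_t**2) / t_idx.size
    var_r = (m_r + alpha * m_r**2) / r_idx.size
    se = np.sqrt(var_t / (m_t + 0.5) ** 2 + var_r / (m_r + 0.5) ** 2) / _LN2
    se = np.maximum(se, 1e-12)
    z = log2_fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(p)
    base_mean = norm.mean(axis=1)
    return [
        DEResult(locus_ids[i], float(log2_fc[i]), float(se[i]), float(p[i]),
                 float(q[i]), float(2.0 ** log2_fc[i]), float(base_mean[i]))
        for i in range(norm.shape[0])
    ]


def results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("locus_id")


def compartment_report(total: Sequence[DEResult],
                       cytoplasmic: Sequence[DEResult]) -> pd.DataFrame:
    """Side-by-side per-locus fold changes in total vs cytoplasmic RNA.

    Loci whose cytoplasmic fold change exceeds the total fold change are
    flagged as export-enriched.  If the locus sets differ a warning is
    raised and the intersection is used.
    """
    ft = results_frame(total)
    fc = results_frame(cytoplasmic)
    common = ft.index.intersection(fc.index)
    if len(common) != len(ft) or len(common) != len(fc):
        import warnings

        warnings.warn("total and cytoplasmic locus sets differ; using intersection",
                      stacklevel=2)
    out = pd.DataFrame(
        {
            "fold_change_total": ft.loc[common, "fold_change"],
            "wald_p_total": ft.loc[common, "wald_p"],
            "fold_change_cytoplasmic": fc.loc[common, "fold_change"],
            "wald_p_cytoplasmic": fc.loc[common, "wald_p"],
        }
    )
    out["export_enriched"] = out["fold_change_cytoplasmic"] > out["fold_change_total"]
    return out


# ---------------------------------------------------------------------------
# Reporter assays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReporterMeasurement:
    """One transfection: p24 in ng/ml, SEAP in relative light units."""

    sample_id: str
    pair: str  # export factor / element combination, e.g. "Rec/prRcRE"
    p24: float
    seap: float

    def __post_init__(self) -> None:
        if self.p24 < 0:
            raise ValueError("p24 cannot be negative")
        if self.seap <= 0:
            raise ValueError("SEAP must be positive (it normalizes transfection efficiency)")


@dataclass(frozen=True)
class RelativeActivity:
    pair: str
    activity: float


def reporter_relative_activity(
    measurements: Sequence[ReporterMeasurement], reference_pair: str = "Rec/prRcRE"
) -> list[RelativeActivity]:
    """SEAP-normalized p24 relative to a reference pair set to 1.

    activity = (p24 / seap) / (p24_ref / seap_ref); the reference pair's own
    activity is exactly 1 by construction.  Invariant to rescaling all SEAP
    values by a common constant.
    """
    ref = [m for m in measurements if m.pair == reference_pair]
    if not ref:
        raise ValueError(f"reference pair {reference_pair!r} not present")
    ref_ratio = float(np.mean([m.p24 / m.seap for m in ref]))
    if ref_ratio == 0:
        raise ValueError("reference pair has zero SEAP-normalized p24")
    return [
        RelativeActivity(m.pair, (m.p24 / m.seap) / ref_ratio) for m in measurements
    ]
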