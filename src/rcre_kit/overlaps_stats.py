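"""FDR filtering of differential-expression tables and three-way set overlap.

Gene lists from independent datasets (e.g. gene regions carrying an RcRE,
genes altered by HIV-1 infection, genes responding to exogenous Rec) are
each thresholded at a Benjamini-Hochberg adjusted p-value and intersected
into the seven exclusive regions of a three-set Venn partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Gene regions reported to contain RcRE-like elements in the GRCh38 screen,
# by HGNC symbol, and their membership in the two external expression
# datasets.  These printed lists are inputs for overlap analysis.
RCRE_CONTAINING_GENES = frozenset({
    "RP4linc", "cFLAR", "ERVK-5", "U9linc", "CNTLN", "C11orf72", "ZNF44",
    "SLC44A5", "CCDC18", "CD48", "CEBPZ", "MAP4K3", "TPRG1", "TMEM64",
    "SLC3A2", "KLRB1", "FN3K", "TULP2", "MMP24",
})
HIV_ALTERED_RCRE_GENES = frozenset({
    "CEBPZ", "SLC44A5", "SLC3A2",
    "MAP4K3", "TPRG1", "TULP2", "CNTLN", "CCDC18", "MMP24", "KLRB1",
    "FN3K", "ZNF44", "CD48",
})
REC_RESPONSIVE_RCRE_GENES = frozenset({"CEBPZ", "SLC44A5", "SLC3A2", "TMEM64"})


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorting p ascending, q_(i) = min_{j>=i} p_(j) * n / j, capped at 1,
    returned in the original input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


@dataclass
class DETable:
    """A differential-expression table: gene id, p-value, q-value.

    If no q column is supplied it is computed with :func:`bh_adjust`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "gene_id" not in df.columns or "p_value" not in df.columns:
            raise ValueError("DETable needs gene_id and p_value columns")
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if ((df["p_value"] < 0) | (df["p_value"] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if "q_value" not in df.columns:
            df = df.copy()
            df["q_value"] = bh_adjust(df["p_value"].to_numpy())
            self.frame = df


def filter_de(table: DETable, alpha: float = 0.01) -> frozenset[str]:
    """Gene ids whose BH-adjusted p-value is strictly below ``alpha``."""
    df = table.frame
    return frozenset(df.loc[df["q_value"] < alpha, "gene_id"])


@dataclass(frozen=True)
class VennPartition:
    """The seven exclusive regions of three sets A, B, C."""

    a_only: frozenset[str]
    b_only: frozenset[str]
    c_only: frozenset[str]
    ab: frozenset[str]
    ac: frozenset[str]
    bc: frozenset[str]
    abc: frozenset[str]

    def regions(self) -> dict[str, frozenset[str]]:
        return {
            "A_only": self.a_only, "B_only": self.b_only, "C_only": self.c_only,
            "AB": self.ab, "AC": self.ac, "BC": self.bc, "ABC": self.abc,
        }

    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for region in self.regions().values():
            out |= region
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"region": name, "count": len(members),
                 "members": ",".join(sorted(members))}
                for name, members in self.regions().items()
            ]
        )


def venn3(a: Iterable[str], b: Iterable[str], c: Iterable[str]) -> VennPartition:
    """Exact exclusive three-set partition (a Venn diagram's seven regions)."""
    sa, sb, sc = frozenset(a), frozenset(b), frozenset(c)
    return VennPartition(
        a_only=sa - sb - sc,
        b_only=sb - sa - sc,
        c_only=sc - sa - sb,
        ab=(sa & sb) - sc,
        ac=(sa & sc) - sb,
        bc=(sb & sc) - sa,
        abc=sa & sb & sc,
    )


def apply_symbol_map(genes: Iterable[str], mapping: dict[str, str]) -> frozenset[str]:
    """Harmonize mixed identifiers via a symbol-to-id table (case-sensitive);
    identifiers absent from the map pass through unchanged."""
    return frozenset(mapping.get(g, g) for g in genes)
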