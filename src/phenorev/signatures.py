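"""Differential-expression signature construction and set algebra.

A signature is the set of genes passing an adjusted-p and fold-change
filter in one contrast.  Signatures can have inducer-responder genes
removed and can be combined across ages/tissues by union/intersection.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GeneEffect",
    "Signature",
    "bh_adjust",
    "build_signature",
    "exclude_responders",
    "combine_signatures",
]


@dataclasses.dataclass(frozen=True)
class GeneEffect:
    """Per-gene summary statistics for one contrast."""

    gene_id: str
    log2fc: float
    lfc_se: float
    pvalue: float
    padj: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.lfc_se > 0:
            raise ValueError(f"lfc_se must be > 0, got {self.lfc_se}")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue must lie in [0, 1], got {self.pvalue}")
        if self.padj is not None and not 0.0 <= self.padj <= 1.0:
            raise ValueError(f"padj must lie in [0, 1], got {self.padj}")


@dataclasses.dataclass(frozen=True)
class Signature:
    """A named gene set with optional per-gene direction of change."""

    name: str
    genes: frozenset
    directions: Optional[Mapping[str, int]] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.directions is not None:
            if set(self.directions) != set(self.genes):
                raise ValueError("directions must cover exactly the member genes")

    def __len__(self) -> int:
        return len(self.genes)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Returns adjusted values aligned with the input positions, clipped to
    [0, 1].  Rejects empty input and p-values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        raise ValueError("bh_adjust requires at least one p-value")
    if np.any(np.isnan(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


TableLike = Union[pd.DataFrame, Sequence[GeneEffect]]


def _as_frame(table: TableLike) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame([dataclasses.asdict(g) for g in table])
    required = {"gene_id", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table is missing columns: {sorted(missing)}")
    return df


def build_signature(
    table: TableLike,
    padj_cut: float = 0.05,
    min_fc: float = 0.20,
    name: str = "signature",
) -> Signature:
    """Select genes with padj < `padj_cut` and a fold change of at least
    `min_fc` in either direction (|log2fc| >= log2(1 + min_fc)).

    A ``padj`` column is used as-is when present; otherwise adjusted
    p-values are computed from ``pvalue`` with :func:`bh_adjust`.
    """
    if not min_fc > 0:
        raise ValueError("min_fc must be > 0")
    df = _as_frame(table)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
    if "padj" in df.columns and df["padj"].notna().all():
        padj = df["padj"].to_numpy(dtype=float)
        padj_source = "provided padj column"
    else:
        padj = bh_adjust(df["pvalue"].to_numpy(dtype=float))
        padj_source = "BH-adjusted pvalue column"
    lfc = df["log2fc"].to_numpy(dtype=float)
    lfc_cut = np.log2(1.0 + min_fc)
    keep = (padj < padj_cut) & (np.abs(lfc) >= lfc_cut)
    members = df.loc[keep, "gene_id"].astype(str)
    directions = {g: (1 if fc > 0 else -1) for g, fc in zip(members, lfc[keep])}
    prov = (
        f"padj<{padj_cut} ({padj_source}); |log2fc|>=log2(1+{min_fc})"
        f"={lfc_cut:.4f}; applied to the provided log2fc column"
    )
    return Signature(name=name, genes=frozenset(members), directions=directions, provenance=prov)


def exclude_responders(sig: Signature, responders: Signature) -> Signature:
    """Remove responder genes (e.g. inducer-only responders) from a signature."""
    kept = sig.genes - responders.genes
    directions = None
    if sig.directions is not None:
        directions = {g: sig.directions[g] for g in kept}
    prov = f"{sig.provenance}; minus {len(sig.genes & responders.genes)} " f"genes from '{responders.name}'"
    return Signature(name=sig.name, genes=frozenset(kept), directions=directions, provenance=prov.strip("; "))


def _merge_directions(genes, a: Signature, b: Signature):
    if a.directions is None or b.directions is None:
        return None
    merged = {}
    for g in genes:
        da = a.directions.get(g)
        db = b.directions.get(g)
        if da is not None and db is not None and da != db:
            return None  # conflicting directions: drop direction annotation
        merged[g] = da if da is not None else db
    return merged


def combine_signatures(a: Signature, b: Signature):
    """Union and intersection of two signatures, with a size report.

    Returns ``(union, intersection, report)`` where ``report`` holds
    |a|, |b|, |a & b| and |a | b|.
    """
    union_genes = frozenset(a.genes | b.genes)
    inter_genes = frozenset(a.genes & b.genes)
    union = Signature(
        name=f"{a.name}|{b.name}",
        genes=union_genes,
        directions=_merge_directions(union_genes, a, b),
        provenance=f"union of '{a.name}' and '{b.name}'",
    )
    inter = Signature(
        name=f"{a.name}&{b.name}",
        genes=inter_genes,
        directions=_merge_directions(inter_genes, a, b),
        provenance=f"intersection of '{a.name}' and '{b.name}'",
    )
    report = {
        "n_a": len(a.genes),
        "n_b": len(b.genes),
        "n_intersection": len(inter_genes),
        "n_union": len(union_genes),
    }
    return union, inter, report
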