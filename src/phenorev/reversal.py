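"""Posterior-probability classification of per-gene effect reversal.

The treatment effect on each gene is modelled as a multiple alpha of the
disease effect on the log2 scale.  Both effect estimates are treated as
independent normal distributions (mean = estimated log2 fold change,
SD = its standard error).  The probability that alpha falls into each of
five classes is computed by quasi-Monte-Carlo integration on a quantile
grid, and each gene is assigned a category plus an overall reversal
probability (ORP = 1 - P[negligible]).
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CLASS_LABELS",
    "ALPHA_BOUNDARIES",
    "GridSpec",
    "GenePair",
    "ReversalResult",
    "classify_alpha",
    "classify_alpha_array",
    "reversal_probs",
    "assign_category",
    "classify_gene",
    "reversal_table",
    "summarize_reversal",
]

#: Class labels ordered from strongest reversal to exacerbation.
CLASS_LABELS: Tuple[str, ...] = ("super", "full", "partial", "negligible", "exacerbation")

#: Ordered cut points on alpha separating the five classes.
ALPHA_BOUNDARIES: Tuple[float, ...] = (-1.3, -0.7, -0.3, 0.3)

_NEGLIGIBLE = CLASS_LABELS.index("negligible")


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Integration grid for the per-gene class probabilities.

    ``placement='quantile'`` puts ``n_points`` nodes at equally spaced
    quantile levels (k - 0.5)/n of each marginal normal; each of the n^2
    grid points then carries equal weight 1/n^2 (the placement itself
    encodes the bivariate density).  ``placement='linear'`` spaces nodes
    equally in effect size over +/- ``span_sd`` standard deviations and
    weights them explicitly by the marginal densities; it is provided
    for sensitivity checks only.
    """

    n_points: int = 121
    placement: str = "quantile"
    span_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if self.placement not in ("quantile", "linear"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclasses.dataclass(frozen=True)
class GenePair:
    """Aligned disease and treatment effect estimates for one gene."""

    gene_id: str
    disease_mean: float
    disease_sd: float
    treat_mean: float
    treat_sd: float

    def __post_init__(self) -> None:
        if not self.disease_sd > 0 or not self.treat_sd > 0:
            raise ValueError("effect SDs must be > 0")


@dataclasses.dataclass(frozen=True)
class ReversalResult:
    gene_id: str
    probs: Tuple[float, float, float, float, float]
    category: str
    orp: float

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")


def classify_alpha(alpha: float) -> str:
    """Class label for a reversal multiplier.

    Boundary values are assigned to the class on the more-negative
    (stronger-reversal) side, e.g. alpha = -1.3 -> 'super'.
    """
    if np.isnan(alpha):
        raise ValueError("alpha must not be NaN")
    return CLASS_LABELS[int(np.searchsorted(ALPHA_BOUNDARIES, alpha, side="left"))]


def classify_alpha_array(alpha: np.ndarray) -> np.ndarray:
    """Vectorized class index (0..4) for an array of finite alphas."""
    return np.searchsorted(ALPHA_BOUNDARIES, alpha, side="left")


def _marginal_nodes(mean: float, sd: float, grid: GridSpec):
    n = grid.n_points
    if grid.placement == "quantile":
        levels = (np.arange(1, n + 1) - 0.5) / n
        nodes = mean + sd * norm.ppf(levels)
        weights = np.full(n, 1.0 / n)
    else:
        z = np.linspace(-grid.span_sd, grid.span_sd, n)
        nodes = mean + sd * z
        weights = norm.pdf(z)
        weights = weights / weights.sum()
    return nodes, weights


def reversal_probs(pair: GenePair, grid: GridSpec = GridSpec()) -> np.ndarray:
    """Five class probabilities for one gene, summing to 1.

    Each of the n x n grid points contributes its weight to the class of
    alpha = treatment node / disease node.  Grid nodes where the disease
    value is exactly zero are counted as exacerbation when the treatment
    value is nonzero (|alpha| infinite, resolved away from reversal) and
    negligible when both are zero.
    """
    d_nodes, d_w = _marginal_nodes(pair.disease_mean, pair.disease_sd, grid)
    t_nodes, t_w = _marginal_nodes(pair.treat_mean, pair.treat_sd, grid)
    D = d_nodes[:, None]
    T = t_nodes[None, :]
    W = np.outer(d_w, t_w)
    W /= W.sum()
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        alpha = T / D
    idx = np.searchsorted(ALPHA_BOUNDARIES, alpha.ravel(), side="left")
    zero_d = np.broadcast_to(D == 0.0, alpha.shape).ravel()
    if zero_d.any():
        t_flat = np.broadcast_to(T, alpha.shape).ravel()
        idx = idx.copy()
        idx[zero_d & (t_flat != 0.0)] = CLASS_LABELS.index("exacerbation")
        idx[zero_d & (t_flat == 0.0)] = _NEGLIGIBLE
    probs = np.bincount(idx, weights=W.ravel(), minlength=5)
    return probs / probs.sum()


def assign_category(probs: Sequence[float], tol: float = 1e-6) -> str:
    """Category from a five-class probability vector.

    If P(negligible) >= 0.05 the gene is called negligibly reversed.
    Otherwise the remaining class with the highest probability wins;
    ties are broken toward the stronger-reversal class.
    """
    p = np.asarray(probs, dtype=float)
    if p.shape != (5,):
        raise ValueError("expected exactly five class probabilities")
    if abs(p.sum() - 1.0) > tol:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    if p[_NEGLIGIBLE] >= 0.05:
        return CLASS_LABELS[_NEGLIGIBLE]
    masked = p.copy()
    masked[_NEGLIGIBLE] = -np.inf
    # np.argmax returns the first maximum; the label order runs from
    # strongest reversal to exacerbation, which implements the tie rule.
    return CLASS_LABELS[int(np.argmax(masked))]


def classify_gene(pair: GenePair, grid: GridSpec = GridSpec()) -> ReversalResult:
    probs = reversal_probs(pair, grid)
    return ReversalResult(
        gene_id=pair.gene_id,
        probs=tuple(float(x) for x in probs),
        category=assign_category(probs),
        orp=float(1.0 - probs[_NEGLIGIBLE]),
    )


def reversal_table(
    disease: pd.DataFrame,
    treatment: pd.DataFrame,
    grid: GridSpec = GridSpec(),
) -> pd.DataFrame:
    """Classify every gene shared by two aligned effect tables.

    Both tables need columns ``gene_id``, ``log2fc`` and ``lfc_se``;
    they are joined on ``gene_id``.  Output columns: one probability per
    class (``p_super`` .. ``p_exacerbation``), ``category`` and ``orp``.
    """
    merged = disease.merge(treatment, on="gene_id", suffixes=("_disease", "_treat"))
    if merged.empty:
        raise ValueError("no shared gene ids between the two tables")
    rows = []
    for rec in merged.itertuples(index=False):
        pair = GenePair(
            gene_id=str(rec.gene_id),
            disease_mean=float(rec.log2fc_disease),
            disease_sd=float(rec.lfc_se_disease),
            treat_mean=float(rec.log2fc_treat),
            treat_sd=float(rec.lfc_se_treat),
        )
        res = classify_gene(pair, grid)
        rows.append((res.gene_id, *res.probs, res.category, res.orp))
    cols = ["gene_id"] + [f"p_{c}" for c in CLASS_LABELS] + ["category", "orp"]
    return pd.DataFrame(rows, columns=cols)


def summarize_reversal(results: Sequence[ReversalResult], orp_cut: float = 0.95) -> dict:
    """Scenario-level summary: category tallies and ORP significance.

    ``n_reversed`` counts genes assigned to any reversal category
    (super, full or partial).  ``n_significant`` counts genes with
    ORP strictly above ``orp_cut``.
    """
    if len(results) == 0:
        raise ValueError("results must be nonempty")
    n = len(results)
    counts = {label: 0 for label in CLASS_LABELS}
    n_sig = 0
    for r in results:
        counts[r.category] += 1
        if r.orp > orp_cut:
            n_sig += 1
    n_reversed = counts["super"] + counts["full"] + counts["partial"]
    return {
        "n_genes": n,
        "category_counts": counts,
        "category_pct": {k: 100.0 * v / n for k, v in counts.items()},
        "n_significant": n_sig,
        "pct_significant": 100.0 * n_sig / n,
        "n_reversed": n_reversed,
        "pct_reversed": 100.0 * n_reversed / n,
        "orp_cut": orp_cut,
    }
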