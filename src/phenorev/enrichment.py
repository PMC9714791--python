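"""Hypergeometric gene-set overrepresentation and reversal summaries."""
from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .reversal import ReversalResult
from .signatures import Signature, bh_adjust

__all__ = ["GeneSetCollection", "EnrichResult", "hypergeom_enrich", "reversal_fraction_by_set"]


@dataclasses.dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against.

    On construction each set is restricted to the universe and sets that
    become empty are dropped, so downstream counts are always consistent
    with the universe.
    """

    sets: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        if len(self.universe) == 0:
            raise ValueError("universe must be nonempty")
        restricted = {}
        for name, members in self.sets.items():
            inside = frozenset(members) & self.universe
            if inside:
                restricted[name] = inside
        object.__setattr__(self, "sets", restricted)

    @classmethod
    def from_gmt(cls, gmt: Mapping[str, Sequence[str]], universe) -> "GeneSetCollection":
        return cls(sets={k: frozenset(v) for k, v in gmt.items()}, universe=frozenset(universe))


@dataclasses.dataclass(frozen=True)
class EnrichResult:
    name: str
    k: int  # overlap between signature and set
    K: int  # set size within the universe
    n: int  # signature size within the universe
    N: int  # universe size
    pvalue: float
    qvalue: float
    gene_ratio: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError("overlap k must satisfy 0 <= k <= min(K, n)")


def hypergeom_enrich(signature: Signature, collection: GeneSetCollection) -> list:
    """Upper-tail hypergeometric overrepresentation of a signature.

    For each set, p = P(overlap >= observed) when n signature genes are
    drawn without replacement from a universe of N containing K set
    members.  q-values are BH-adjusted over all tested sets; results are
    sorted by gene_ratio (= k/n) descending.
    """
    sig_genes = frozenset(signature.genes) & collection.universe
    if not sig_genes:
        raise ValueError("signature restricted to the universe is empty")
    if not collection.sets:
        raise ValueError("collection has no nonempty sets after restriction")
    N = len(collection.universe)
    n = len(sig_genes)
    names, ks, Ks, ps = [], [], [], []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(sig_genes & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        names.append(name)
        ks.append(k)
        Ks.append(K)
        ps.append(min(p, 1.0))
    qs = bh_adjust(ps)
    results = [
        EnrichResult(
            name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            pvalue=p,
            qvalue=float(q),
            gene_ratio=k / n,
        )
        for name, k, K, p, q in zip(names, ks, Ks, ps, qs)
    ]
    results.sort(key=lambda r: (-r.gene_ratio, r.pvalue, r.name))
    return results


def reversal_fraction_by_set(
    results_by_scenario: Mapping[str, Sequence[ReversalResult]],
    collection: GeneSetCollection,
    signature: Signature,
    orp_cut: float = 0.95,
) -> pd.DataFrame:
    """Per-(gene set, scenario) percentage of signature genes with
    ORP > ``orp_cut`` — the data behind a radar plot of reversal by
    functional category.

    Every signature gene must have a result in every scenario; missing
    genes raise with the offending ids.  Sets disjoint from the
    signature are dropped with a warning.
    """
    sig_genes = frozenset(signature.genes)
    orp: Dict[str, Dict[str, float]] = {}
    for scenario, results in results_by_scenario.items():
        lookup = {r.gene_id: r.orp for r in results}
        missing = sorted(sig_genes - set(lookup))
        if missing:
            raise KeyError(
                f"scenario {scenario!r} lacks reversal results for "
                f"{len(missing)} signature genes, e.g. {missing[:5]}"
            )
        orp[scenario] = lookup
    rows = {}
    for name, members in collection.sets.items():
        in_set = sorted(sig_genes & members)
        if not in_set:
            warnings.warn(f"gene set {name!r} shares no genes with the signature; skipped")
            continue
        rows[name] = {
            scenario: 100.0 * np.mean([orp[scenario][g] > orp_cut for g in in_set])
            for scenario in results_by_scenario
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(results_by_scenario))
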