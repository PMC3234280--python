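"""Hypergeometric over-representation of feature classes in gene sets.

For a feature class of ``n`` genes drawn from a universe of ``N`` analyzable
genes, a set with ``K`` universe members and ``k`` class members scores
``p = P(X >= k)`` under Hypergeometric(N, K, n) — the exact upper tail —
with BH q-values across the tested sets.  One-sided: only over-representation
is scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .associations import bh_adjust
from .io import GeneSetCollection

__all__ = ["EnrichmentRecord", "hypergeometric_enrichment", "enrichment_to_frame"]


@dataclass(frozen=True)
class EnrichmentRecord:
    set_id: str
    description: str
    k: int  # class genes in the set
    K: int  # universe genes in the set
    n: int  # class size (within universe)
    N: int  # universe size
    p_value: float
    q_value: float


def hypergeometric_enrichment(
    class_genes,
    gene_sets: GeneSetCollection,
    universe,
    fdr_level: float = 0.05,
) -> list[EnrichmentRecord]:
    """Score every gene set for over-representation of ``class_genes``.

    ``class_genes`` must be a subset of ``universe``; each set is intersected
    with the universe first and sets disjoint from it are dropped with a
    warning.  Records come back sorted by q-value (then set id).
    """
    universe = set(universe)
    class_set = set(class_genes)
    if not universe:
        raise ValueError("empty universe")
    if not class_set:
        raise ValueError("empty feature class")
    stray = class_set - universe
    if stray:
        raise ValueError(
            f"class genes outside the universe: {sorted(stray)[:5]}"
        )
    big_n = len(universe)
    n = len(class_set)
    rows = []
    for sid, (desc, members) in gene_sets.sets.items():
        in_universe = members & universe
        if not in_universe:
            warnings.warn(f"gene set {sid!r} is disjoint from the universe; dropped")
            continue
        big_k = len(in_universe)
        k = len(in_universe & class_set)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((sid, desc, k, big_k, p))
    if not rows:
        return []
    q = bh_adjust([r[4] for r in rows])
    records = [
        EnrichmentRecord(sid, desc, k, big_k, n, big_n, p, float(qv))
        for (sid, desc, k, big_k, p), qv in zip(rows, q)
    ]
    records.sort(key=lambda r: (r.q_value, r.p_value, r.set_id))
    return records


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "description": r.description,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in records
        ],
        columns=["set_id", "description", "k", "K", "n", "N", "p_value", "q_value"],
    )
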