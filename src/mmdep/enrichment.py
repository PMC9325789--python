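"""Hypergeometric over-representation of a query gene set against
annotation terms, with Benjamini-Hochberg control across terms."""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .containers import GeneSetCollection
from .survival import bh_adjust


def hypergeom_test(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), inclusive of k.

    X counts annotated genes in a draw of ``n`` from a universe of
    ``big_n`` containing ``big_k`` annotated genes.
    """
    if not (0 <= big_k <= big_n and 0 <= n <= big_n):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    if k > min(big_k, n):
        raise ValueError(f"overlap k={k} exceeds min(K={big_k}, n={n})")
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(hypergeom.sf(k - 1, big_n, big_k, n))


def enrich_all(
    query: set[str], sets: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """Test every term for over-representation of ``query`` genes.

    Terms are intersected with the universe first; emptied terms are
    excluded from testing and from the BH family.  Results are sorted by
    ascending p with BH q-values over all tested terms.
    """
    if not query:
        raise ValueError("query gene set is empty")
    extra = set(query) - set(universe)
    if extra:
        raise ValueError(f"query genes outside universe: {sorted(extra)[:5]}")
    restricted = sets.restrict(set(universe))
    big_n, n = len(universe), len(query)
    rows = []
    for term in restricted:
        members = restricted.members[term]
        k = len(query & members)
        rows.append(
            {
                "term_id": term,
                "term_name": restricted.names[term],
                "overlap": k,
                "term_size": len(members),
                "query_size": n,
                "universe_size": big_n,
                "p": hypergeom_test(k, len(members), n, big_n),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "overlap", "term_size",
            "query_size", "universe_size", "p",
        ],
    )
    if len(result):
        q, _ = bh_adjust(result["p"].to_numpy())
        result["q"] = q
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        result["q"] = []
    return result
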