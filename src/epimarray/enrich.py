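"""Gene-set over-representation with a two-sided Fisher's exact test.

For a query of ``n`` genes drawn from a universe of ``N`` genes, a set
with ``K`` members in the universe and ``k`` in the query gives the 2x2
table [[k, n-k], [K-k, N-n-K+k]].  The two-sided P value follows the
minimum-likelihood convention: the sum of hypergeometric probabilities of
every table with the same margins whose probability does not exceed that
of the observed table.  The summation here is exact — integer-weight
enumeration over the support, divided once at the end — so it agrees with
an exhaustive enumeration oracle to full precision.  The enrichment score
is -log10(P).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the universe of symbols eligible for testing."""

    sets: dict
    universe: frozenset

    def __post_init__(self):
        object.__setattr__(self, "universe", frozenset(self.universe))
        clipped = {}
        for name, members in self.sets.items():
            inter = frozenset(members) & self.universe
            if inter:
                clipped[name] = inter
            else:
                logger.warning("gene set %r empty after universe intersection; dropped", name)
        object.__setattr__(self, "sets", clipped)

    @classmethod
    def from_sets(cls, sets: dict, universe=None, universe_mode: str = "gmt"):
        """Build a collection; universe 'gmt' = union of set members,
        or pass an explicit iterable (e.g. array symbols in >= 1 set)."""
        if universe is None:
            if universe_mode != "gmt":
                raise ValueError("explicit universe required unless universe_mode='gmt'")
            universe = frozenset().union(*[frozenset(s) for s in sets.values()]) if sets else frozenset()
        return cls(sets={k: frozenset(v) for k, v in sets.items()}, universe=frozenset(universe))


def fisher_test(k: int, n_query: int, K: int, N: int) -> float:
    """Exact two-sided Fisher P for the table [[k, n-k], [K-k, N-n-K+k]].

    Integer hypergeometric enumeration with the minimum-likelihood
    two-sided rule; ties in probability are exact integer comparisons.
    """
    if not (0 <= K <= N and 0 <= n_query <= N):
        raise ValueError("margins must satisfy 0 <= K, n_query <= N")
    lo, hi = max(0, n_query + K - N), min(n_query, K)
    if not lo <= k <= hi:
        raise ValueError(f"k={k} outside hypergeometric support [{lo}, {hi}]")
    # weight(j) = C(K, j) * C(N-K, n-j); P(j) = weight(j) / C(N, n)
    weights = [math.comb(K, j) * math.comb(N - K, n_query - j) for j in range(lo, hi + 1)]
    observed = weights[k - lo]
    numerator = sum(w for w in weights if w <= observed)
    total = sum(weights)  # == C(N, n_query)
    if numerator == total:
        return 1.0
    return numerator / total


def enrichment_score(p: float) -> float:
    """-log10(P); 1.3010 at P = 0.05."""
    return -math.log10(p)


def enrich(query, collection: GeneSetCollection, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Over-representation of a gene list against every set in the collection.

    Out-of-universe query symbols are dropped with a logged count.  Rows
    are ranked by score descending (equivalently ascending P), ties broken
    by set name; columns: set, k, n_query, K, N, p, bh, score, significant.
    Significance uses raw P < alpha; the BH column is informational.
    """
    query = set(query)
    dropped = query - collection.universe
    if dropped:
        logger.warning("%d query symbol(s) outside universe dropped", len(dropped))
    query &= collection.universe
    if not query:
        logger.warning("empty query after universe intersection")
        return pd.DataFrame(columns=["set", "k", "n_query", "K", "N", "p", "bh",
                                     "score", "significant"])
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(query & members)
        p = fisher_test(k, n, K, N)
        rows.append({"set": name, "k": k, "n_query": n, "K": K, "N": N,
                     "p": p, "score": enrichment_score(p), "significant": p < alpha})
    out = pd.DataFrame(rows)
    out["bh"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out.sort_values(["p", "set"], ascending=[True, True]).reset_index(drop=True)
    return out[["set", "k", "n_query", "K", "N", "p", "bh", "score", "significant"]]


#: Default quadrant unions tested per comparison: all upregulated
#: m6A-associated genes, their split by methylation direction, and the
#: downregulated mirror.
DEFAULT_QUADRANT_GROUPS = {
    "up": ("Hyper-Up", "Hypo-Up"),
    "down": ("Hyper-Down", "Hypo-Down"),
    "hyper_up": ("Hyper-Up",),
    "hypo_up": ("Hypo-Up",),
}


def enrich_quadrant_groups(assignments: pd.DataFrame, collection: GeneSetCollection,
                           groups: dict | None = None,
                           alpha: float = DEFAULT_ALPHA) -> dict:
    """Run enrichment on configured unions of quadrants.

    ``assignments`` is the output of ``integrate.assign_quadrants`` (needs
    gene_symbol and quadrant columns).  Quadrant exclusivity makes union
    sizes additive.  Returns {group name: enrichment frame}; empty unions
    yield empty frames with a log note.
    """
    from .integrate import QUADRANTS
    groups = DEFAULT_QUADRANT_GROUPS if groups is None else groups
    results = {}
    for name, quadrants in groups.items():
        unknown = set(quadrants) - set(QUADRANTS)
        if unknown:
            raise ValueError(f"unknown quadrant(s) in group {name!r}: {sorted(unknown)}")
        genes = set(assignments.loc[assignments["quadrant"].isin(quadrants), "gene_symbol"])
        if not genes:
            logger.info("quadrant group %r empty; no enrichment run", name)
            results[name] = enrich(set(), collection, alpha)
            continue
        results[name] = enrich(genes, collection, alpha)
    return results
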