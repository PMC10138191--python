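"""Hypergeometric over-representation of a gene list against a GMT
collection, with BH-FDR and top-k ranking by -log10(FDR).

One-sided over-representation only: p is the upper hypergeometric tail
P(X >= k) for an overlap of k between a query of size n and a set of size
K inside a universe of size N. Set members are intersected with the
universe before testing; the ranking statistic uses log10 by convention
(``log_base`` can change it).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .errors import DataError

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def enrich(
    query: list[str],
    universe: list[str],
    collection: dict[str, tuple[str, list[str]]],
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Over-representation test for every set in the collection.

    Query genes outside the universe are dropped with a logged count;
    sets empty after intersection with the universe are not tested. FDR
    is BH across all tested sets; rows sort by (fdr, p, set_name).
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    q = set(query)
    dropped = q - uni
    if dropped:
        logger.info("dropped %d query gene(s) not in the universe", len(dropped))
        q &= uni
    N, n = len(uni), len(q)
    rows = []
    for name, (_desc, members) in collection.items():
        mem = set(members) & uni
        K = len(mem)
        if K == 0:
            continue
        overlap = sorted(mem & q)
        k = len(overlap)
        rows.append((name, N, K, n, k, hypergeom_upper_tail(k, K, n, N), overlap))
    res = pd.DataFrame(
        rows, columns=["set_name", "universe_size", "set_size", "query_size", "overlap", "p_value", "genes"]
    )
    if res.empty:
        res["fdr"] = res["neg_log_fdr"] = []
        return res
    res["fdr"] = bh_adjust(res["p_value"].to_numpy())
    res["neg_log_fdr"] = -np.log(res["fdr"]) / math.log(log_base)
    res = res.sort_values(["fdr", "p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    return res


def top_categories(results: pd.DataFrame, m: int = 10) -> pd.DataFrame:
    """First m results of an `enrich` table (fewer if the collection is
    smaller)."""
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    return results.head(m).reset_index(drop=True)
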