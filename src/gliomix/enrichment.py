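"""Fisher's-exact over-representation of gene lists in gene-set collections.

One-sided hypergeometric tail test of a query gene list against each set in
a collection, with BH FDR across the collection. The universe defaults to
whatever the caller measured (typically the probe-mapped genes shared by
all platforms); set membership is intersected with the universe before
testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import SignatureCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    query_size: int
    set_size: int
    universe_size: int
    odds_ratio: float
    p_value: float
    fdr: float
    overlap_genes: list[str]


def fisher_enrichment(query: list[str], collection: SignatureCollection,
                      universe: list[str]) -> list[EnrichmentResult]:
    """One-sided (over-representation) Fisher test per set, BH FDR across
    the collection; results sorted by p ascending.

    Query genes outside the universe are logged and dropped; each set is
    intersected with the universe. p = P(X >= overlap) for X hypergeometric
    with the 2x2 table margins.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise ValueError("empty universe")
    uni_set = set(uni)
    q = list(dict.fromkeys(g for g in query if g in uni_set))
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.warning("%d query genes outside the universe dropped", dropped)
    if not q:
        raise ValueError("query empty after intersecting with universe")
    n_uni, n_query = len(uni), len(q)
    q_set = set(q)
    results = []
    for set_name, genes in collection.sets.items():
        members = [g for g in genes if g in uni_set]
        overlap_genes = sorted(q_set & set(members))
        k, m = len(overlap_genes), len(members)
        p = float(hypergeom.sf(k - 1, n_uni, m, n_query))
        a, b = k, m - k
        c, d = n_query - k, (n_uni - m) - (n_query - k)
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan)
        results.append(EnrichmentResult(
            set_name=set_name, overlap=k, query_size=n_query, set_size=m,
            universe_size=n_uni, odds_ratio=float(odds), p_value=p,
            fdr=np.nan, overlap_genes=overlap_genes))
    fdr = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, qv in zip(results, fdr):
        r.fdr = float(qv)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = vars(r).copy()
        row["overlap_genes"] = ";".join(row["overlap_genes"])
        rows.append(row)
    return pd.DataFrame(rows)


def overlap_matrix(result_lists: dict[str, list[EnrichmentResult]],
                   fdr_max: float = 0.05) -> pd.DataFrame:
    """Counts of sets significant (FDR < fdr_max) in each pair of lists.

    Diagonal holds per-list significant counts. All lists must have been
    computed against the same collection.
    """
    names = list(result_lists)
    set_universe = None
    significant = {}
    for name in names:
        sets_here = {r.set_name for r in result_lists[name]}
        if set_universe is None:
            set_universe = sets_here
        elif sets_here != set_universe:
            raise ValueError("result lists computed against different "
                             "collections")
        significant[name] = {r.set_name for r in result_lists[name]
                             if r.fdr < fdr_max}
    out = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a in names:
        for b in names:
            out.loc[a, b] = len(significant[a] & significant[b])
    return out
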