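"""Over-representation analysis (ORA) of a query gene set against GMT
libraries.

The statistic is the exact hypergeometric upper tail: with a universe of
size M, an effective term of size K = |term ∩ universe| and a query of size
n, the p-value is P[X ≥ k] for the observed overlap k. Benjamini–Hochberg
adjustment is applied within each library. For compatibility with
Enrichr-style rankings a combined score c = |z · ln p| is also reported,
where z measures the deviation of a term's observed rank from its rank
distribution under seeded random queries of the same size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetLibrary

logger = logging.getLogger(__name__)

#: Smallest p-value forwarded to the log in the combined score.
P_FLOOR = float(np.nextafter(0, 1))


def ora_pvalue(query: set[str], term: set[str], universe: set[str]) -> float:
    """Exact hypergeometric upper-tail probability of the observed overlap.

    ``query`` must be a subset of ``universe``; the term is intersected
    with the universe before testing.
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    eff_term = term & universe
    k = len(query & eff_term)
    # P[X >= k] = sf(k - 1)
    return float(hypergeom.sf(k - 1, len(universe), len(eff_term), len(query)))


def randomized_pvalue(
    overlap: int, universe_size: int, term_size: int, query_size: int, u: float
) -> float:
    """Randomized (uniformized) p-value P[X > k] + u·P[X = k].

    Under the null this statistic is exactly U(0,1), unlike the raw
    upper-tail p-value of a discrete test, which is superuniform. Used for
    calibration checks.
    """
    rv = hypergeom(universe_size, term_size, query_size)
    return float(rv.sf(overlap) + u * rv.pmf(overlap))


def adjust_bh(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    if not p_values:
        return []
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-value {p} outside (0, 1]")
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(v) for v in q]


def combined_score(p_value: float, rank_z: float) -> float:
    """Enrichr-style combined score c = |z · ln p| (0 when p = 1)."""
    if p_value <= 0:
        raise ValueError("p-value must be positive; floor upstream at P_FLOOR")
    if not math.isfinite(rank_z):
        raise ValueError("rank z-score must be finite")
    return abs(rank_z * math.log(p_value))


@dataclass
class EnrichmentResult:
    term_id: str
    description: str
    term_size: int
    overlap_size: int
    universe_size: int
    query_size: int
    p_value: float
    q_value: float
    rank_z: float
    combined_score: float
    overlap_genes: frozenset[str]


def _rank_terms(pvals: dict[str, float]) -> dict[str, int]:
    order = sorted(pvals, key=lambda t: (pvals[t], t))
    return {t: i + 1 for i, t in enumerate(order)}


def enrich(
    query: set[str],
    library: GeneSetLibrary,
    universe: set[str] | None = None,
    n_permutations: int = 100,
    rng: np.random.Generator | int | None = None,
) -> list[EnrichmentResult]:
    """ORA of a query gene set against every term of one library.

    The universe defaults to the union of all genes in the library; the
    query is restricted to it. Results are BH-adjusted within the library
    and sorted by p ascending, ties by term id. ``rng`` seeds the random
    queries used for the rank z-score.
    """
    if not library.terms:
        raise ValueError("library is empty")
    if universe is None:
        universe = set(library.all_genes)
    eff_query = query & universe
    if not eff_query:
        raise ValueError(
            "query is disjoint from the universe — check gene symbol casing "
            "(symbols are compared upper-cased)"
        )
    if len(eff_query) < len(query):
        logger.info("restricted query to universe: %d of %d genes kept",
                    len(eff_query), len(query))
    rng = np.random.default_rng(rng)

    pvals = {t.term_id: ora_pvalue(eff_query, set(t.genes), universe) for t in library.terms}
    observed_rank = _rank_terms(pvals)

    # rank z-score: deviation from ranks under random same-size queries
    # (n_permutations=0 skips the permutations; z and combined score are 0)
    universe_arr = np.array(sorted(universe))
    rank_samples: dict[str, list[int]] = {t.term_id: [] for t in library.terms}
    for _ in range(n_permutations):
        perm_query = set(rng.choice(universe_arr, size=len(eff_query), replace=False))
        perm_p = {t.term_id: ora_pvalue(perm_query, set(t.genes), universe) for t in library.terms}
        for term_id, rank in _rank_terms(perm_p).items():
            rank_samples[term_id].append(rank)
    rank_z: dict[str, float] = {}
    for term_id, samples in rank_samples.items():
        if not samples:
            rank_z[term_id] = 0.0
            continue
        mu = float(np.mean(samples))
        sd = float(np.std(samples))
        rank_z[term_id] = (mu - observed_rank[term_id]) / sd if sd > 0 else 0.0

    term_order = [t.term_id for t in library.terms]
    qvals = dict(zip(term_order, adjust_bh([max(pvals[t], P_FLOOR) for t in term_order])))

    results = []
    for t in library.terms:
        p = pvals[t.term_id]
        overlap = eff_query & (t.genes & universe)
        results.append(
            EnrichmentResult(
                term_id=t.term_id,
                description=t.description,
                term_size=len(t.genes & universe),
                overlap_size=len(overlap),
                universe_size=len(universe),
                query_size=len(eff_query),
                p_value=p,
                q_value=qvals[t.term_id],
                rank_z=rank_z[t.term_id],
                combined_score=combined_score(max(p, P_FLOOR), rank_z[t.term_id]),
                overlap_genes=frozenset(overlap),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_table(results: list[EnrichmentResult]):
    """Flatten results to a DataFrame (term, size, overlap, p, q, score, genes)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "description": [r.description for r in results],
            "term_size": [r.term_size for r in results],
            "overlap_size": [r.overlap_size for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "combined_score": [r.combined_score for r in results],
            "overlap_genes": [",".join(sorted(r.overlap_genes)) for r in results],
        }
    )


def bubble_data(results: list[EnrichmentResult], top_k: int = 20):
    """Top-k terms encoded for bubble plots: term, gene count, q-value."""
    import pandas as pd

    top = results[:top_k]
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in top],
            "gene_count": [r.overlap_size for r in top],
            "q_value": [r.q_value for r in top],
        }
    )
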