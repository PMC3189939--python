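"""Gene-axis functional group enrichment analysis (FGA).

The classic over-representation test: given a query gene list (e.g. the
genes up-regulated in one sample group), a functional gene set, and the
annotated universe, the overlap is scored with the one-sided hypergeometric
upper tail.  The universe is the set of genes surviving the intensity
filter, deduplicated by symbol; functional sets are intersected with the
universe before counting, so annotation outside the assayed genes cannot
alter the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

from .io_formats import GeneSet, GeneSetCollection
from .stats_core import benjamini_hochberg, tail_p

logger = logging.getLogger(__name__)

__all__ = ["FgaResult", "fga_enrich_set", "fga_enrich_all"]


@dataclass(frozen=True)
class FgaResult:
    set_id: str
    set_name: str
    N_T: int  # annotated genes in the universe
    N_F: int  # functional-group genes in the universe
    N_G: int  # query gene-list size
    N_C: int  # overlap
    p_value: float
    fdr: float | None = None
    significant: bool | None = None


def fga_enrich_set(
    query_genes: Iterable[str], functional_group: GeneSet, universe: Iterable[str]
) -> FgaResult:
    """Hypergeometric over-representation p for one functional group.

    ``query_genes`` must be a subset of ``universe`` (a query gene missing
    from the universe would silently distort the null and is rejected).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes absent from universe: {sorted(stray)[:5]}")
    group = set(functional_group.genes) & universe
    overlap = query & group
    p = tail_p(
        population=len(universe),
        successes=len(group),
        draws=len(query),
        observed=len(overlap),
    )
    return FgaResult(
        set_id=functional_group.set_id,
        set_name=functional_group.name,
        N_T=len(universe),
        N_F=len(group),
        N_G=len(query),
        N_C=len(overlap),
        p_value=p,
    )


def fga_enrich_all(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_set_size: int = 5,
    fdr_threshold: float = 0.05,
) -> list[FgaResult]:
    """FGA over a collection with BH correction across the tested sets.

    Sets with fewer than ``min_set_size`` genes in the universe are skipped
    before testing and therefore do not count toward the BH denominator.
    Results are ordered ascending by p, ties by set id.
    """
    universe = set(universe)
    query = set(query_genes)
    results: list[FgaResult] = []
    for set_id in sorted(collection.sets):
        gs = collection[set_id]
        if len(set(gs.genes) & universe) < min_set_size:
            continue
        results.append(fga_enrich_set(query, gs, universe))
    if not results:
        logger.warning("fga_enrich_all: no gene set met the minimum size of %d", min_set_size)
        return []
    qvals = benjamini_hochberg([r.p_value for r in results])
    results = [
        replace(r, fdr=float(q), significant=bool(q < fdr_threshold))
        for r, q in zip(results, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results
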