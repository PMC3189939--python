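"""Coverage analysis with Fisher's exact test (CAFET).

Where FGA asks "are pathway genes over-represented among differentially
expressed genes?", CAFET turns the table sideways and asks "are the samples
carrying a pathway dysregulation signature over-represented in the sample
group of interest?".  A sample carries the signature for a gene when at
least one of the gene's probes deviates beyond a fold threshold from that
probe's median across all samples (above 2.5x for up, below 0.5x for down
— asymmetric because baseline noise limits how far expression can fall).
For a functional group the signature is carried by any sample flagged for
at least one member gene, i.e. the union of the per-gene flagged-sample
sets.  Coverage counts are then scored with the same one-sided
hypergeometric tail as FGA:

    p = P(X >= S_C)  with population S_T, class size S_G, draws S_P

where S_T is the cohort size, S_G the size of group 1, S_P the flagged
samples and S_C the flagged samples falling in group 1 (S_FP / S_FC for the
union counts of a functional group).

Because a single dysregulated member per sample suffices to cover that
sample, CAFET detects pathways whose members are altered in different
samples — a pattern invisible to gene-axis enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .clustering import SampleGrouping
from .io_formats import ExpressionMatrix, GeneSetCollection
from .stats_core import benjamini_hochberg, tail_p

logger = logging.getLogger(__name__)

Direction = Literal["up", "down"]

__all__ = [
    "DysregulationFlags",
    "CafetGeneResult",
    "CafetGroupResult",
    "flag_samples_per_gene",
    "cafet_gene",
    "cafet_group",
    "cafet_all",
    "cafet_genes_all",
]


@dataclass(frozen=True)
class DysregulationFlags:
    """Samples in which ``gene`` deviates beyond the fold threshold."""

    gene: str
    direction: Direction
    flagged_samples: frozenset[str]
    sample_universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.flagged_samples <= self.sample_universe:
            raise ValueError("flagged samples outside the sample universe")


@dataclass(frozen=True)
class CafetGeneResult:
    gene: str
    direction: Direction
    S_T: int
    S_G: int
    S_P: int
    S_C: int
    p_value: float
    fdr: float | None = None


@dataclass(frozen=True)
class CafetGroupResult:
    set_id: str
    set_name: str
    direction: Direction
    n_genes_contributing: int
    S_T: int
    S_G: int
    S_FP: int  # size of the union of member flagged-sample sets
    S_FC: int  # union members falling in group 1
    p_value: float
    fdr: float | None = None
    eligible: bool = True


def flag_samples_per_gene(
    matrix: ExpressionMatrix,
    gene: str,
    direction: Direction,
    up_fold: float = 2.5,
    down_fold: float = 0.5,
    reference_samples: Iterable[str] | None = None,
) -> DysregulationFlags:
    """Flag samples where any probe of ``gene`` crosses the fold threshold.

    The per-probe baseline is the median across all samples (or, when
    ``reference_samples`` is given, the mean over those samples — the
    alternative baseline of comparing against the control group's average).
    A sample is flagged up when any probe value is strictly greater than
    ``up_fold`` x baseline, down when strictly below ``down_fold`` x
    baseline.  A probe with baseline 0 can never flag down and flags up for
    any positive value; this degenerate case is logged.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    probes = matrix.gene_to_probes().get(gene)
    if not probes:
        raise KeyError(f"gene {gene!r} has no mapped probe in the matrix")
    sub = matrix.values.loc[probes]
    if reference_samples is None:
        baseline = sub.median(axis=1)
    else:
        ref = sorted(set(reference_samples))
        missing = set(ref) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"reference samples not in matrix: {sorted(missing)[:5]}")
        baseline = sub[ref].mean(axis=1)
    if (baseline == 0).any():
        logger.warning(
            "gene %s: probe(s) with zero baseline; they cannot flag 'down' and flag "
            "'up' for any positive value",
            gene,
        )
    if direction == "up":
        hits = sub.gt(up_fold * baseline, axis=0)
    else:
        hits = sub.lt(down_fold * baseline, axis=0)
    flagged = frozenset(hits.columns[hits.any(axis=0)])
    return DysregulationFlags(
        gene=gene,
        direction=direction,
        flagged_samples=flagged,
        sample_universe=frozenset(matrix.sample_ids),
    )


def cafet_gene(flags: DysregulationFlags, grouping: SampleGrouping) -> CafetGeneResult:
    """Single-gene CAFET: enrichment of flagged samples in group 1."""
    if flags.sample_universe != grouping.all_samples:
        raise ValueError("flags and grouping cover different sample universes")
    S_T = len(flags.sample_universe)
    S_G = len(grouping.group1)
    S_P = len(flags.flagged_samples)
    S_C = len(flags.flagged_samples & grouping.group1)
    p = tail_p(population=S_T, successes=S_G, draws=S_P, observed=S_C)
    return CafetGeneResult(
        gene=flags.gene, direction=flags.direction, S_T=S_T, S_G=S_G, S_P=S_P, S_C=S_C, p_value=p
    )


def cafet_group(
    member_flags: Sequence[DysregulationFlags],
    grouping: SampleGrouping,
    min_contributing_genes: int = 5,
    set_id: str = "",
    set_name: str = "",
) -> CafetGroupResult:
    """Functional-group CAFET via the union of member flagged-sample sets.

    A member gene "contributes" when it flags at least one sample; groups
    with fewer than ``min_contributing_genes`` contributing members are
    returned with ``eligible=False`` and must be excluded from BH.
    """
    if not member_flags:
        raise ValueError("member_flags is empty")
    directions = {f.direction for f in member_flags}
    if len(directions) > 1:
        raise ValueError(f"mixed directions in one group: {sorted(directions)}")
    universes = {f.sample_universe for f in member_flags}
    if len(universes) > 1:
        raise ValueError("member flags cover different sample universes")
    (universe,) = universes
    if universe != grouping.all_samples:
        raise ValueError("flags and grouping cover different sample universes")
    union: set[str] = set()
    contributing = 0
    for f in member_flags:
        if f.flagged_samples:
            contributing += 1
            union |= f.flagged_samples
    S_T = len(universe)
    S_G = len(grouping.group1)
    S_FP = len(union)
    S_FC = len(union & grouping.group1)
    p = tail_p(population=S_T, successes=S_G, draws=S_FP, observed=S_FC)
    return CafetGroupResult(
        set_id=set_id,
        set_name=set_name,
        direction=next(iter(directions)),
        n_genes_contributing=contributing,
        S_T=S_T,
        S_G=S_G,
        S_FP=S_FP,
        S_FC=S_FC,
        p_value=p,
        eligible=contributing >= min_contributing_genes,
    )


def _flags_for_genes(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    direction: Direction,
    up_fold: float,
    down_fold: float,
    reference_samples: Iterable[str] | None,
) -> dict[str, DysregulationFlags]:
    present = matrix.genes()
    return {
        g: flag_samples_per_gene(
            matrix, g, direction, up_fold=up_fold, down_fold=down_fold,
            reference_samples=reference_samples,
        )
        for g in sorted(set(genes) & present)
    }


def cafet_all(
    matrix: ExpressionMatrix,
    grouping: SampleGrouping,
    collection: GeneSetCollection,
    direction: Direction = "up",
    up_fold: float = 2.5,
    down_fold: float = 0.5,
    min_contributing_genes: int = 5,
    fdr_threshold: float = 0.05,
    reference_samples: Iterable[str] | None = None,
) -> list[CafetGroupResult]:
    """Group-level CAFET over a gene-set collection with BH correction.

    Per-gene flags are computed once and shared across all groups that
    contain the gene.  BH runs across eligible groups only; ineligible
    groups are dropped from the output.  Results are ordered ascending by p,
    ties by set id.
    """
    all_genes = set()
    for gs in collection:
        all_genes |= gs.genes
    flag_cache = _flags_for_genes(
        matrix, all_genes, direction, up_fold, down_fold, reference_samples
    )
    results: list[CafetGroupResult] = []
    for set_id in sorted(collection.sets):
        gs = collection[set_id]
        member_flags = [flag_cache[g] for g in sorted(gs.genes) if g in flag_cache]
        if not member_flags:
            continue
        res = cafet_group(
            member_flags,
            grouping,
            min_contributing_genes=min_contributing_genes,
            set_id=gs.set_id,
            set_name=gs.name,
        )
        if res.eligible:
            results.append(res)
    if not results:
        logger.warning(
            "cafet_all: no group had >= %d contributing genes", min_contributing_genes
        )
        return []
    qvals = benjamini_hochberg([r.p_value for r in results])
    results = [replace(r, fdr=float(q)) for r, q in zip(results, qvals)]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def cafet_genes_all(
    matrix: ExpressionMatrix,
    grouping: SampleGrouping,
    gene_list: Iterable[str],
    direction: Direction = "up",
    up_fold: float = 2.5,
    down_fold: float = 0.5,
    reference_samples: Iterable[str] | None = None,
) -> list[CafetGeneResult]:
    """Gene-by-gene CAFET over a candidate list, BH within the list.

    Duplicated gene symbols are tested once; genes absent from the matrix
    are dropped with a logged warning.
    """
    genes = sorted(set(gene_list))
    present = matrix.genes()
    missing = [g for g in genes if g not in present]
    if missing:
        logger.warning("cafet_genes_all: %d genes absent from matrix: %s ...",
                       len(missing), missing[:5])
    flag_cache = _flags_for_genes(matrix, genes, direction, up_fold, down_fold, reference_samples)
    results = [cafet_gene(flag_cache[g], grouping) for g in sorted(flag_cache)]
    if not results:
        return []
    qvals = benjamini_hochberg([r.p_value for r in results])
    results = [replace(r, fdr=float(q)) for r, q in zip(results, qvals)]
    results.sort(key=lambda r: (r.p_value, r.gene))
    return results
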