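"""Probe filtering, log transformation and two-group differential expression.

The differential-expression rule implemented here is the conventional
microarray one: per probe, a Welch (unequal-variance) two-sample t-test on
log2 intensities, Benjamini-Hochberg correction across all tested probes,
and a probe "passes" when FDR < 0.05 and the ratio of linear-scale group
means exceeds 2.5-fold.  A gene is called differentially expressed when at
least one of its probes passes; direction follows the sign of that probe's
mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import SampleGrouping
from .io_formats import ExpressionMatrix
from .stats_core import benjamini_hochberg

__all__ = [
    "filter_probes_by_max_intensity",
    "log2_transform",
    "select_top_variance_probes",
    "DifferentialExpressionTable",
    "differential_expression",
]


def filter_probes_by_max_intensity(
    matrix: ExpressionMatrix, threshold: float = 100.0
) -> ExpressionMatrix:
    """Drop probes whose maximum intensity across samples falls below ``threshold``.

    A probe whose max equals the threshold exactly is retained ("below"
    means strictly less).  Samples are never removed.
    """
    keep = matrix.values.max(axis=1) >= threshold
    return matrix.subset_probes(list(matrix.values.index[keep]))


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Return log2(value + pseudocount) as a probe-by-sample DataFrame."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    arr = matrix.values.to_numpy()
    if pseudocount == 0 and (arr == 0).any():
        raise ValueError("zero intensity with zero pseudocount: log2 undefined")
    return np.log2(matrix.values + pseudocount)


def select_top_variance_probes(log_values: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the ``k`` probes with the largest across-sample variance.

    Convenience for clustering on a high-variance subset; ties are broken by
    probe id so the selection is deterministic.
    """
    var = log_values.var(axis=1, ddof=1)
    order = sorted(log_values.index, key=lambda p: (-var[p], p))
    return log_values.loc[order[:k]]


@dataclass
class DifferentialExpressionTable:
    """Per-probe DE records plus the derived gene-level calls.

    ``records`` columns: probe_id, gene, mean_g1, mean_g2, fold_change,
    direction, p_value, fdr, is_de.  ``fold_change`` is the ratio of linear
    group means stored as max/min (>= 1); ``direction`` is "group1" or
    "group2" for the group with the larger mean.
    """

    records: pd.DataFrame
    up_in_group1: set[str]
    up_in_group2: set[str]


def differential_expression(
    matrix: ExpressionMatrix,
    grouping: SampleGrouping,
    fold_threshold: float = 2.5,
    fdr_threshold: float = 0.05,
    pseudocount: float = 1.0,
) -> DifferentialExpressionTable:
    """Two-group differential expression over all probes of ``matrix``.

    Welch's t is computed on log2(value + pseudocount); the fold gate uses
    linear-scale group means (strictly greater than ``fold_threshold``).
    Probes with zero variance in both groups get p = 1 when the means agree
    and p = 0 (a degenerate, perfectly separated probe) when they differ.
    """
    g1 = sorted(grouping.group1)
    g2 = sorted(grouping.group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples for a t-test")
    missing = (set(g1) | set(g2)) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"grouping references unknown samples: {sorted(missing)[:5]}")

    log_vals = log2_transform(matrix, pseudocount)
    a = log_vals[g1].to_numpy()
    b = log_vals[g2].to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    p = np.nan_to_num(p, nan=1.0)

    fdr = benjamini_hochberg(p)

    mean_g1 = matrix.values[g1].mean(axis=1).to_numpy()
    mean_g2 = matrix.values[g2].mean(axis=1).to_numpy()
    hi = np.maximum(mean_g1, mean_g2)
    lo = np.minimum(mean_g1, mean_g2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
    direction = np.where(mean_g1 >= mean_g2, "group1", "group2")

    is_de = (fdr < fdr_threshold) & (fold > fold_threshold)

    probes = matrix.probe_ids
    records = pd.DataFrame(
        {
            "probe_id": probes,
            "gene": [matrix.probe_to_gene.get(pr) for pr in probes],
            "mean_g1": mean_g1,
            "mean_g2": mean_g2,
            "fold_change": fold,
            "direction": direction,
            "p_value": p,
            "fdr": fdr,
            "is_de": is_de,
        }
    )

    passing = records[records["is_de"] & records["gene"].notna()]
    up1 = set(passing.loc[passing["direction"] == "group1", "gene"])
    up2 = set(passing.loc[passing["direction"] == "group2", "gene"])
    return DifferentialExpressionTable(records=records, up_in_group1=up1, up_in_group2=up2)
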