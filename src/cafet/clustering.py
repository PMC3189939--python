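"""Hierarchical clustering of samples and the two-group cut.

Samples (columns of the log-scale expression grid) are clustered by
average-linkage (UPGMA) agglomeration on pairwise Euclidean distances.
Cutting the dendrogram at its root yields the two primary sample groups
used everywhere downstream.  Columns are ordered lexicographically by
sample id before the distance computation, so results are invariant to the
input column order (and tie-breaking is platform-stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["SampleGrouping", "Dendrogram", "hierarchical_cluster", "cut_into_two_groups"]


@dataclass(frozen=True)
class SampleGrouping:
    """Disjoint bipartition of the cohort into group1 and group2."""

    group1: frozenset[str]
    group2: frozenset[str]
    subgroups: dict[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("both groups must be non-empty")
        if self.group1 & self.group2:
            raise ValueError("groups overlap")

    @property
    def all_samples(self) -> frozenset[str]:
        return self.group1 | self.group2

    @property
    def n_total(self) -> int:
        return len(self.group1) + len(self.group2)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration result: leaf sample ids plus a SciPy linkage matrix.

    Leaf ``i`` in the linkage matrix is ``leaf_ids[i]``; internal node
    ``n + j`` is the cluster formed by merge row ``j``.
    """

    leaf_ids: tuple[str, ...]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError(f"linkage must have {n - 1} merge rows for {n} leaves")

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    def leaves_under(self, node: int) -> set[str]:
        """Sample ids in the subtree rooted at linkage node index ``node``."""
        n = len(self.leaf_ids)
        out: set[str] = set()
        stack = [node]
        while stack:
            k = stack.pop()
            if k < n:
                out.add(self.leaf_ids[k])
            else:
                row = self.linkage[k - n]
                stack.extend((int(row[0]), int(row[1])))
        return out


def hierarchical_cluster(log_values: pd.DataFrame) -> Dendrogram:
    """UPGMA (average-linkage) clustering of samples in probe space.

    ``log_values`` is probe x sample (as produced by
    :func:`cafet.preprocess.log2_transform`); Euclidean distances are taken
    between sample columns.
    """
    if log_values.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    ordered = sorted(log_values.columns)
    X = log_values[ordered].to_numpy().T  # samples x probes
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    return Dendrogram(leaf_ids=tuple(ordered), linkage=Z)


def cut_into_two_groups(
    dendrogram: Dendrogram,
    anchor: str | None = None,
    sample_labels: dict[str, str] | None = None,
) -> SampleGrouping:
    """Split the cohort at the dendrogram root into group1 / group2.

    Which side is called group1 is a labeling decision, controlled by
    ``anchor``:

    * a sample id — its subtree becomes group1;
    * a class label (with ``sample_labels`` given) — the subtree holding the
      majority of that label becomes group1;
    * ``None`` — the smaller subtree is group1 (ties broken toward the
      subtree containing the lexicographically smallest sample id).
    """
    n = len(dendrogram.leaf_ids)
    root = dendrogram.linkage[-1]
    side_a = dendrogram.leaves_under(int(root[0]))
    side_b = dendrogram.leaves_under(int(root[1]))

    def pick_group1() -> set[str]:
        if anchor is not None:
            if anchor in side_a:
                return side_a
            if anchor in side_b:
                return side_b
            if sample_labels is not None:
                count_a = sum(1 for s in side_a if sample_labels.get(s) == anchor)
                count_b = sum(1 for s in side_b if sample_labels.get(s) == anchor)
                if count_a != count_b:
                    return side_a if count_a > count_b else side_b
                raise ValueError(f"anchor label {anchor!r} is tied between subtrees")
            raise ValueError(f"anchor {anchor!r} is neither a sample id nor a known label")
        if len(side_a) != len(side_b):
            return side_a if len(side_a) < len(side_b) else side_b
        return side_a if min(side_a) < min(side_b) else side_b

    g1 = pick_group1()
    g2 = (side_a | side_b) - g1
    assert len(g1) + len(g2) == n
    return SampleGrouping(group1=frozenset(g1), group2=frozenset(g2))
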