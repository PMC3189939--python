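"""Per-sample scoring of an up/down expression signature.

Each gene's expression is summarized as the average of its probe rows on
the log2 scale, then standardized across samples (z-score with the n-1
standard deviation; a zero-variance gene maps to an all-zero row).  A
sample's signature score is the sum of standardized values over the
up-genes minus the sum over the down-genes, so positive scores mark samples
that resemble the signature and the score is invariant to per-gene scaling
of the raw intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .preprocess import log2_transform

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureDefinition",
    "normalize_expression",
    "score_samples",
    "read_signature_tsv",
    "write_scores_tsv",
]


@dataclass(frozen=True)
class SignatureDefinition:
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.up_genes) & set(self.down_genes)
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)[:5]}")
        if not (self.up_genes or self.down_genes):
            raise ValueError("signature is empty")


def normalize_expression(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Gene-by-sample grid of standardized log2 expression.

    Probe rows of a gene are averaged on the log2 scale, then each gene row
    is z-scored across samples (ddof=1).  Genes with zero across-sample
    variance become all-zero rows.
    """
    log_vals = log2_transform(matrix, pseudocount)
    gene_index = matrix.gene_to_probes()
    rows = {}
    for gene in sorted(gene_index):
        avg = log_vals.loc[gene_index[gene]].mean(axis=0)
        sd = avg.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            rows[gene] = pd.Series(0.0, index=avg.index)
        else:
            rows[gene] = (avg - avg.mean()) / sd
    return pd.DataFrame(rows).T.reindex(columns=matrix.sample_ids)


def score_samples(matrix: ExpressionMatrix, signature: SignatureDefinition) -> pd.DataFrame:
    """Score every sample against the signature.

    Returns a DataFrame with columns sample_id, score, n_up_used,
    n_down_used (signature genes absent from the matrix are dropped with a
    warning; at least one must be present).
    """
    z = normalize_expression(matrix)
    up = [g for g in signature.up_genes if g in z.index]
    down = [g for g in signature.down_genes if g in z.index]
    dropped = (set(signature.up_genes) - set(up)) | (set(signature.down_genes) - set(down))
    if dropped:
        logger.warning("score_samples: %d signature genes absent from matrix: %s ...",
                       len(dropped), sorted(dropped)[:5])
    if not up and not down:
        raise ValueError("no signature gene present in the matrix")
    score = pd.Series(0.0, index=z.columns)
    if up:
        score = score + z.loc[up].sum(axis=0)
    if down:
        score = score - z.loc[down].sum(axis=0)
    return pd.DataFrame(
        {
            "sample_id": z.columns,
            "score": score.to_numpy(),
            "n_up_used": len(up),
            "n_down_used": len(down),
        }
    )


def read_signature_tsv(path: str | Path) -> SignatureDefinition:
    """Read a two-column signature file: gene TAB direction(up|down)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene", "direction"]:
        raise ValueError(f"{path}: expected columns gene, direction")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"{path}: direction must be up or down, got {sorted(bad)}")
    return SignatureDefinition(
        up_genes=tuple(df.loc[df["direction"] == "up", "gene"]),
        down_genes=tuple(df.loc[df["direction"] == "down", "gene"]),
    )


def write_scores_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False)
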