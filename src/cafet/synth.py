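"""Seeded generator of microarray-like cohorts with planted pathway signal.

The generator emulates the statistical shape the enrichment machinery
assumes: positive, right-skewed linear intensities (log-normal cells,
log2-domain Gaussian noise), optional multi-probe genes, a two-group sample
partition, and a gene-set collection containing one planted pathway plus
size-matched decoy sets.

Two planted-dysregulation regimes mirror the two situations that separate
sample-axis from gene-axis enrichment:

* ``concentrated`` — every planted-set gene is scaled by ``planted_fold``
  in every group-1 sample (most pathway members altered in most case
  samples; both FGA and CAFET should fire);
* ``distributed`` — each group-1 sample has exactly one planted-set gene
  scaled, assigned round-robin (every case sample carries the signature,
  but each through a different member; only CAFET should fire);
* ``null`` — no modification (calibration runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import SampleGrouping
from .io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = ["SynthConfig", "make_probe_map", "generate_cohort", "PLANTED_SET_ID"]

PLANTED_SET_ID = "PLANTED"


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation parameters.

    Defaults describe a 1000-gene, 100-sample cohort with a 20-gene planted
    pathway at 4-fold dysregulation over a log-normal baseline
    (log2 intensities ~ Normal(8, 0.5)), half the samples in group 1.
    """

    n_genes: int = 1000
    probes_per_gene: int = 1
    n_samples: int = 100
    group1_fraction: float = 0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 0.5
    planted_set_size: int = 20
    planted_fold: float = 4.0
    regime: str = "distributed"
    n_decoy_sets: int = 20
    seed: int = 17

    def __post_init__(self) -> None:
        if min(self.n_genes, self.probes_per_gene, self.n_samples, self.planted_set_size) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.group1_fraction < 1:
            raise ValueError("group1_fraction must lie strictly between 0 and 1")
        if self.regime not in ("concentrated", "distributed", "null"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime != "null" and self.planted_fold <= 1:
            raise ValueError("planted_fold must exceed 1 for non-null regimes")
        if self.planted_set_size > self.n_genes:
            raise ValueError("planted_set_size exceeds n_genes")


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def make_probe_map(config: SynthConfig) -> dict[str, str]:
    """Deterministic probe->gene map, ``{gene}_p{k}`` per probe."""
    return {
        f"{gene}_p{k}": gene
        for gene in _gene_names(config.n_genes)
        for k in range(1, config.probes_per_gene + 1)
    }


def generate_cohort(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, SampleGrouping, GeneSetCollection]:
    """Generate (matrix, grouping, gene sets) reproducibly from the seed.

    Baseline cells are 2**Normal(baseline_log2_mean, baseline_log2_sd) i.i.d.
    per probe and sample; the planted perturbation multiplies all probes of
    the affected gene in the affected samples by ``planted_fold``.  The
    returned collection holds the planted set (id ``PLANTED``) and
    ``n_decoy_sets`` size-matched decoys drawn from non-planted genes.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    samples = _sample_names(config.n_samples)
    probe_map = make_probe_map(config)
    probes = list(probe_map)

    log2_vals = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=(len(probes), len(samples))
    )
    values = pd.DataFrame(np.power(2.0, log2_vals), index=probes, columns=samples)

    n_group1 = max(1, min(config.n_samples - 1, round(config.n_samples * config.group1_fraction)))
    group1 = samples[:n_group1]
    group2 = samples[n_group1:]

    planted = genes[: config.planted_set_size]
    gene_rows = {g: [p for p in probes if probe_map[p] == g] for g in genes}

    if config.regime == "concentrated":
        for g in planted:
            values.loc[gene_rows[g], group1] *= config.planted_fold
    elif config.regime == "distributed":
        for j, s in enumerate(group1):
            g = planted[j % len(planted)]
            values.loc[gene_rows[g], s] *= config.planted_fold

    matrix = ExpressionMatrix(
        values=values,
        probe_to_gene=dict(probe_map),
        sample_labels={s: ("case" if s in set(group1) else "control") for s in samples},
    )
    grouping = SampleGrouping(group1=frozenset(group1), group2=frozenset(group2))

    collection = GeneSetCollection()
    collection.add(
        GeneSet(set_id=PLANTED_SET_ID, name="planted pathway", genes=frozenset(planted))
    )
    non_planted = np.array(genes[config.planted_set_size:])
    if config.n_decoy_sets > 0 and len(non_planted) < config.planted_set_size:
        raise ValueError(
            f"cannot draw decoy sets of size {config.planted_set_size} from "
            f"{len(non_planted)} non-planted genes"
        )
    width = len(str(config.n_decoy_sets))
    for d in range(1, config.n_decoy_sets + 1):
        members = rng.choice(non_planted, size=config.planted_set_size, replace=False)
        collection.add(
            GeneSet(
                set_id=f"DECOY_{d:0{width}d}",
                name=f"decoy set {d}",
                genes=frozenset(members.tolist()),
            )
        )
    return matrix, grouping, collection
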