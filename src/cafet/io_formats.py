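"""Text-format readers and writers plus the core in-memory containers.

Supported formats
-----------------
* Expression TSV: header ``probe_id[<TAB>gene_symbol]<TAB>sample1...``, one
  probe per row, linear-scale non-negative intensities.
* GMT gene-set collections (``set_id TAB description TAB gene...``).
* NCBI gene2go annotation tables (tab-separated, ``#`` comment lines).
* Flat KEGG membership lists (``pathway_id TAB gene_symbol`` per line).
* Sample grouping TSV (``sample_id TAB group [TAB subgroup]``).
* Enrichment result tables, ordered ascending by p then set id.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_gene2go",
    "read_kegg_gene_list",
    "read_grouping_tsv",
    "write_grouping_tsv",
    "write_results_tsv",
]


@dataclass
class ExpressionMatrix:
    """Probe-by-sample matrix of linear-scale intensities.

    ``values`` is a probe x sample DataFrame; ``probe_to_gene`` maps probe id
    to gene symbol (many probes per gene allowed; probes without a mapping
    carry ``None`` and are invisible to gene-level operations).
    """

    values: pd.DataFrame
    probe_to_gene: dict[str, str | None] = field(default_factory=dict)
    sample_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("intensities must be numeric")
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            raise ValueError("intensities must be finite and non-negative")
        unknown = set(self.probe_to_gene) - set(idx)
        if unknown:
            raise ValueError(f"probe map references unknown probes: {sorted(unknown)[:5]}")
        # probes absent from the map get an explicit null gene
        for probe in idx:
            self.probe_to_gene.setdefault(probe, None)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genes(self) -> set[str]:
        """Distinct gene symbols with at least one mapped probe."""
        return {g for g in self.probe_to_gene.values() if g is not None}

    def gene_to_probes(self) -> dict[str, list[str]]:
        cached = getattr(self, "_gene_index", None)
        if cached is not None:
            return cached
        out: dict[str, list[str]] = {}
        for probe in self.values.index:
            gene = self.probe_to_gene.get(probe)
            if gene is not None:
                out.setdefault(gene, []).append(probe)
        self._gene_index = out  # lazy index; probe set never mutates in place
        return out

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        keep = [p for p in self.values.index if p in set(probes)]
        return ExpressionMatrix(
            values=self.values.loc[keep].copy(),
            probe_to_gene={p: self.probe_to_gene.get(p) for p in keep},
            sample_labels=None if self.sample_labels is None else dict(self.sample_labels),
        )


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise ValueError("set_id must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets keyed by unique set id."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, gs in self.sets.items():
            if set_id != gs.set_id:
                raise ValueError(f"key {set_id!r} does not match set id {gs.set_id!r}")

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self.sets:
            raise ValueError(f"duplicate set id: {gene_set.set_id!r}")
        self.sets[gene_set.set_id] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, gene_map_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a probe-by-sample expression TSV.

    The first column holds probe ids; if the second column is headed
    ``gene_symbol`` it provides the probe-to-gene map, otherwise a separate
    two-column TSV may be supplied via ``gene_map_path``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "probe_id":
        raise ValueError(f"{path}: first column must be 'probe_id', got {df.columns[0]!r}")
    df = df.set_index("probe_id")
    probe_to_gene: dict[str, str | None] = {}
    if len(df.columns) and df.columns[0] == "gene_symbol":
        gene_col = df["gene_symbol"]
        df = df.drop(columns=["gene_symbol"])
        for probe, gene in gene_col.items():
            probe_to_gene[probe] = None if pd.isna(gene) or gene == "" else str(gene)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric value in row {bad.idxmax()!r}, column {col!r}"
            )
        if numeric.isna().any():
            raise ValueError(f"{path}: missing value in column {col!r}")
        if (numeric < 0).any():
            row = numeric.index[numeric < 0][0]
            raise ValueError(f"{path}: negative intensity in row {row!r}, column {col!r}")
        df[col] = numeric.astype(float)
    df.index.name = None
    if gene_map_path is not None:
        gm = pd.read_csv(gene_map_path, sep="\t", dtype=str)
        if gm.shape[1] < 2:
            raise ValueError(f"{gene_map_path}: expected two columns (probe, gene)")
        for probe, gene in zip(gm.iloc[:, 0], gm.iloc[:, 1]):
            if probe in df.index:
                probe_to_gene[probe] = None if pd.isna(gene) else str(gene)
    return ExpressionMatrix(values=df, probe_to_gene=probe_to_gene)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression TSV (with a gene_symbol column when any probe is mapped)."""
    df = matrix.values.copy()
    if any(g is not None for g in matrix.probe_to_gene.values()):
        genes = [matrix.probe_to_gene.get(p) or "" for p in df.index]
        df.insert(0, "gene_symbol", genes)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: ``set_id TAB description TAB gene...`` per line."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3")
            set_id, name, *genes = fields
            genes = [g for g in genes if g]
            collection.add(GeneSet(set_id=set_id, name=name, genes=frozenset(genes)))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection.sets):
            gs = collection[set_id]
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")


def read_gene2go(path: str | Path, tax_id: int) -> GeneSetCollection:
    """Read NCBI's gene2go dialect, restricted to one taxon.

    Columns: tax_id, GeneID, GO_ID, Evidence, Qualifier, GO_term, PubMed,
    Category.  Rows whose Qualifier contains ``NOT`` negate the annotation and
    are excluded.  Malformed rows are skipped with a logged count.
    """
    members: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                skipped += 1
                continue
            try:
                row_tax = int(fields[0])
            except ValueError:
                skipped += 1
                continue
            if row_tax != tax_id:
                continue
            gene_id, go_id, qualifier, go_term = fields[1], fields[2], fields[4], fields[5]
            if "NOT" in qualifier.split("|"):
                continue
            members.setdefault(go_id, set()).add(gene_id)
            names.setdefault(go_id, go_term)
    if skipped:
        logger.warning("read_gene2go: skipped %d malformed rows in %s", skipped, path)
    collection = GeneSetCollection()
    for go_id in sorted(members):
        collection.add(GeneSet(set_id=go_id, name=names[go_id], genes=frozenset(members[go_id])))
    return collection


def read_kegg_gene_list(path: str | Path) -> GeneSetCollection:
    """Read a flat pathway membership list: ``pathway_id TAB gene_symbol`` per line."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'pathway_id<TAB>gene'")
            members.setdefault(fields[0], set()).add(fields[1])
    collection = GeneSetCollection()
    for pid in sorted(members):
        collection.add(GeneSet(set_id=pid, name=pid, genes=frozenset(members[pid])))
    return collection


# ---------------------------------------------------------------------------
# Sample groupings
# ---------------------------------------------------------------------------

def read_grouping_tsv(path: str | Path):
    """Read ``sample_id TAB group [TAB subgroup]`` into a SampleGrouping."""
    from .clustering import SampleGrouping

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: expected columns sample_id, group")
    g1 = frozenset(df.loc[df["group"] == "1", "sample_id"])
    g2 = frozenset(df.loc[df["group"] == "2", "sample_id"])
    bad = set(df["group"]) - {"1", "2"}
    if bad:
        raise ValueError(f"{path}: group values must be 1 or 2, got {sorted(bad)}")
    subgroups = None
    if "subgroup" in df.columns and df["subgroup"].notna().any():
        subgroups = {
            label: frozenset(sub["sample_id"])
            for label, sub in df.dropna(subset=["subgroup"]).groupby("subgroup")
        }
    return SampleGrouping(group1=g1, group2=g2, subgroups=subgroups)


def write_grouping_tsv(grouping, path: str | Path) -> None:
    rows = []
    sub_of = {}
    if grouping.subgroups:
        for label, ids in grouping.subgroups.items():
            for s in ids:
                sub_of[s] = label
    for s in sorted(grouping.group1):
        rows.append({"sample_id": s, "group": "1", "subgroup": sub_of.get(s, "")})
    for s in sorted(grouping.group2):
        rows.append({"sample_id": s, "group": "2", "subgroup": sub_of.get(s, "")})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def _result_sort_key(record: Mapping) -> tuple:
    p = record.get("p_value", math.nan)
    key_id = record.get("set_id", record.get("gene", ""))
    return (math.inf if p is None or (isinstance(p, float) and math.isnan(p)) else p, key_id)


def write_results_tsv(results: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a homogeneous sequence of result dataclasses as a sorted TSV.

    Rows are ordered ascending by p-value, ties broken by set/gene id; the
    column order is the dataclass field order, so output is deterministic.
    ``columns`` supplies the header when ``results`` is empty.
    """
    if results:
        types = {type(r) for r in results}
        if len(types) > 1:
            raise ValueError(f"mixed result types: {sorted(t.__name__ for t in types)}")
        rows = [dataclasses.asdict(r) for r in results]
        columns = [f.name for f in dataclasses.fields(results[0])]
        rows.sort(key=_result_sort_key)
        df = pd.DataFrame(rows, columns=columns)
        df["p_value"] = df["p_value"].map(lambda v: f"{v:.6g}" if pd.notna(v) else "")
        if "fdr" in df.columns:
            df["fdr"] = df["fdr"].map(lambda v: f"{v:.6g}" if pd.notna(v) else "")
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, sep="\t", index=False)
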