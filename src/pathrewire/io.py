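"""Readers and writers for the external formats the pipeline touches.

Supported inputs: gene expression matrices as delimited text (genes x
samples, TAB or comma, auto-detected), gene sets in Broad-dialect GMT,
TF->TG regulatory edge lists, and plain-text seed gene lists.  Outputs are
TAB-separated tables plus a ``run.json`` with parameters and seeds.

Gene identifiers are treated as opaque strings: the caller is responsible
for using one consistent ID space (e.g. Entrez or symbols) across the
expression matrices, gene sets and the regulatory network.  Harmonization
inside the package is a pure set intersection and never invents IDs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = ("case", "control")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """A genes x samples matrix of (assumed log-scale) expression values.

    Wraps a :class:`pandas.DataFrame` whose index holds unique gene IDs and
    whose columns hold unique sample IDs.  All values must be finite; missing
    values are rejected at construction.  An optional per-sample ``group``
    label in ``{"case", "control"}`` is carried when a single combined file
    holds both conditions.
    """

    def __init__(self, values: pd.DataFrame, group: pd.Series | None = None):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID {dup!r} in expression matrix")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r} in expression matrix")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {values.index[i]!r}, "
                f"sample {values.columns[j]!r}"
            )
        if group is not None:
            group = group.reindex(values.columns)
            bad = set(group.dropna().unique()) - set(VALID_GROUPS)
            if bad or group.isna().any():
                raise ValueError(
                    f"unknown group label(s) {sorted(map(str, bad)) or 'missing'}; "
                    f"expected one of {VALID_GROUPS}"
                )
        self.values = values.astype(float)
        self.group = group

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.group)

    def split_groups(self) -> tuple["ExpressionMatrix", "ExpressionMatrix"]:
        """Split a combined matrix into (case, control) by the group labels."""
        if self.group is None:
            raise ValueError("matrix carries no group labels to split on")
        case = self.values.loc[:, self.group == "case"]
        ctrl = self.values.loc[:, self.group == "control"]
        return ExpressionMatrix(case), ExpressionMatrix(ctrl)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    description: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PathwayCollection:
    """An ordered collection of uniquely named gene sets."""

    entries: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.entries]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate pathway ID {dup!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.entries:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def subset_to_universe(
        self, universe: Iterable[str], min_genes: int = 6
    ) -> "PathwayCollection":
        """Intersect every gene set with ``universe``; drop sets that fall
        below ``min_genes`` mapped members."""
        uni = set(universe)
        kept = []
        for p in self.entries:
            g = p.genes & uni
            if len(g) >= min_genes:
                kept.append(Pathway(p.pathway_id, p.description, frozenset(g)))
        dropped = len(self.entries) - len(kept)
        if dropped:
            logger.info("dropped %d pathway(s) with < %d mapped genes", dropped, min_genes)
        return PathwayCollection(kept)

    def deduplicate(self) -> "PathwayCollection":
        """Optional redundancy pass: among pathways with identical gene sets,
        keep the first.  Off by default in the pipeline."""
        seen: set[frozenset[str]] = set()
        kept = []
        for p in self.entries:
            if p.genes in seen:
                continue
            seen.add(p.genes)
            kept.append(p)
        return PathwayCollection(kept)


@dataclass
class RegulatoryNetwork:
    """Directed TF -> TG edges from a background regulatory network."""

    edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        loops = {e for e in self.edges if e[0] == e[1]}
        if loops:
            raise ValueError(f"self-regulation pair(s) not allowed: {sorted(loops)[:3]}")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.edges}

    def targets_of(self, tf: str) -> set[str]:
        return {tg for t, tg in self.edges if t == tf}


@dataclass
class GeneList:
    """An ordered, duplicate-free list of gene IDs (used for disease seeds)."""

    ids: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("gene list is empty")
        seen: set[str] = set()
        uniq = []
        for g in self.ids:
            if g not in seen:
                seen.add(g)
                uniq.append(g)
        self.ids = uniq

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    """Auto-detect the delimiter among TAB and comma from the header line."""
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def read_expression(
    path: str | Path, group_map: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Read a delimited genes x samples expression matrix.

    First column holds gene IDs, the header row holds sample IDs.  Duplicate
    gene rows and non-numeric or missing cells are hard errors; the error
    message names the offending gene/sample.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.columns.size == 0:
        raise ValueError(f"malformed header in {path}: no sample columns")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene row {dup!r} in {path}")
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(num.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        cell = raw.iat[i, j]
        raise ValueError(
            f"non-numeric cell {cell!r} at gene {raw.index[i]!r} "
            f"(row {i + 2}), sample {raw.columns[j]!r} (column {j + 2}) in {path}"
        )
    group = None
    if group_map is not None:
        missing = [s for s in num.columns if s not in group_map]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        group = pd.Series({s: group_map[s] for s in num.columns})
    return ExpressionMatrix(num, group)


def read_gmt(
    path: str | Path, min_genes: int = 6, on_duplicate: str = "error"
) -> PathwayCollection:
    """Read a Broad-dialect GMT file: ``name TAB description TAB gene...``.

    Duplicate genes within a line are collapsed.  Gene sets with fewer than
    ``min_genes`` unique members are dropped (drop count logged).  Duplicate
    pathway names raise by default; ``on_duplicate="keep_first"`` keeps the
    first occurrence with a warning instead.
    """
    path = Path(path)
    entries: list[Pathway] = []
    names: set[str] = set()
    dropped = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {ln} has {len(fields)} field(s); need >= 3")
            name, desc, *genes = fields
            if name in names:
                if on_duplicate == "keep_first":
                    warnings.warn(f"duplicate pathway {name!r}; keeping first")
                    continue
                raise ValueError(f"duplicate pathway name {name!r} at line {ln}")
            uniq = frozenset(g for g in genes if g)
            if len(uniq) < min_genes:
                dropped += 1
                continue
            names.add(name)
            entries.append(Pathway(name, desc, uniq))
    if not entries and dropped == 0:
        raise ValueError(f"empty GMT file: {path}")
    if dropped:
        logger.info("dropped %d gene set(s) with < %d genes", dropped, min_genes)
    return PathwayCollection(entries)


def read_regulatory_network(path: str | Path) -> RegulatoryNetwork:
    """Read a 2+ column delimited TF, TG[, source] edge list.

    Duplicate pairs are collapsed; self-loops are dropped with a warning.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    edges: set[tuple[str, str]] = set()
    n_rows = 0
    n_loops = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) < 2:
                fields = line.split()  # whitespace fallback
            if len(fields) < 2:
                raise ValueError(f"regulatory network line {ln}: fewer than 2 columns")
            tf, tg = fields[0], fields[1]
            n_rows += 1
            if tf == tg:
                n_loops += 1
                continue
            edges.add((tf, tg))
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop row(s) from {path}")
    logger.info("read %d rows, %d unique TF->TG edges from %s", n_rows, len(edges), path)
    return RegulatoryNetwork(edges)


def read_gene_list(path: str | Path) -> GeneList:
    """Read a plain-text gene list, one ID per line."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return GeneList(ids)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

EDGE_COLUMNS = [
    "gene_i", "gene_j", "r_case", "r_ctrl", "rewire", "Z", "p", "adj_p",
    "delta", "regulatory", "tf", "tg",
]
PATHWAY_COLUMNS = [
    "pathway", "T", "m", "M", "enrich_p", "enrich_adj_p", "R", "Dr", "Dy",
    "perm_p", "perm_adj_p", "disease_score", "altered", "differentially_regulated",
    "rank", "tfs", "tgs",
]
GENE_COLUMNS = [
    "gene", "logFC", "de_adj_p", "degree", "closeness", "transitivity",
    "pagerank", "cs", "local_rewiring", "affinity",
]


def write_outputs(results, out_dir: str | Path) -> dict[str, Path]:
    """Write ``edges.tsv``, ``pathways.tsv``, ``genes.tsv`` and ``run.json``.

    ``results`` is a fitted :class:`~pathrewire.model.PathwayRewiringResults`
    (or anything exposing ``edges``/``pathways``/``genes`` DataFrames and a
    ``run_info`` dict).  Empty result sets produce headers-only files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame, cols in (
        ("edges", results.edges, EDGE_COLUMNS),
        ("pathways", results.pathways, PATHWAY_COLUMNS),
        ("genes", results.genes, GENE_COLUMNS),
    ):
        df = frame.copy() if frame is not None else pd.DataFrame(columns=cols)
        for c in cols:
            if c not in df.columns:
                df[c] = pd.NA
        df = df[cols]
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p
    p = out / "run.json"
    with open(p, "w") as fh:
        json.dump(results.run_info, fh, indent=2, sort_keys=True, default=str)
    paths["run"] = p
    return paths
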