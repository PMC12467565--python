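"""Readers/writers for the external formats the pipeline touches.

Canonical interchange formats are deliberately plain text: counts and
taxonomy as TSV, sample metadata and function panels as CSV, trees as
newick, networks as GraphML/GEXF. A BIOM v1 (JSON) table is accepted
read-only. Readers validate and reject — they never silently repair.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import skbio

from .exceptions import FormatError, MetadataError, UsageError

log = logging.getLogger(__name__)

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]

__all__ = [
    "OtuTable",
    "FunctionMatrix",
    "read_otu_table",
    "write_otu_table",
    "read_biom_json",
    "read_newick",
    "write_newick",
    "read_function_matrix",
    "write_function_matrix",
    "write_network",
    "read_network",
    "RANKS",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """A taxa × samples count matrix with taxonomy and sample metadata.

    ``counts`` is indexed by taxon id with sample ids as columns;
    ``taxonomy`` maps taxon id to ranked lineage columns (kingdom..genus);
    ``metadata`` is indexed by sample id and must carry a ``group`` column
    (free strings; "HB1".."HB4" are a convention of the study design, not a
    requirement) and may carry ``altitude_m`` and ``replicate``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise FormatError("duplicate taxon ids in count table")
        if c.columns.duplicated().any():
            raise FormatError("duplicate sample ids in count table")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric counts")
        if np.isnan(arr.astype(float)).any():
            raise FormatError("missing values in count table")
        if (arr < 0).any():
            raise FormatError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("counts must be integers")
        self.counts = c.astype(np.int64)
        missing = set(c.columns) - set(self.metadata.index)
        if missing:
            raise MetadataError(f"samples missing from metadata: {sorted(missing)}")
        if "group" not in self.metadata.columns:
            raise MetadataError("metadata must have a 'group' column")
        if self.metadata.loc[list(c.columns), "group"].isna().any():
            raise MetadataError("every sample needs a group label")
        # taxa absent from the taxonomy table get an Unclassified lineage
        tax = self.taxonomy.reindex(c.index)
        self.taxonomy = tax.fillna("Unclassified")

    # -- convenience views -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def groups(self) -> pd.Series:
        """group label per sample, in column order."""
        return self.metadata.loc[self.sample_ids, "group"]

    def group_samples(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.groups.items():
            out.setdefault(str(g), []).append(s)
        return out

    def lineage_at(self, rank: str) -> pd.Series:
        if rank not in self.taxonomy.columns:
            raise UsageError(
                f"rank {rank!r} not in taxonomy columns {list(self.taxonomy.columns)}"
            )
        return self.taxonomy[rank]

    def subset_samples(self, samples: list[str]) -> "OtuTable":
        return OtuTable(
            self.counts[samples].copy(),
            self.taxonomy.copy(),
            self.metadata.loc[samples].copy(),
        )


@dataclass
class FunctionMatrix:
    """Plot × indicator panel of ecosystem-function measurements.

    ``indicator_groups`` maps each indicator to a function group (by default
    one of EF-C, EF-N, EF-P, EF-Prod); ``plot_groups`` maps each plot to its
    altitude group; ``units`` is informational.
    """

    values: pd.DataFrame
    indicator_groups: dict[str, str]
    plot_groups: pd.Series
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise FormatError("duplicate plot ids in function matrix")
        if v.columns.duplicated().any():
            raise FormatError("duplicate indicator names in function matrix")
        unmapped = set(v.columns) - set(self.indicator_groups)
        if unmapped:
            raise MetadataError(f"indicators without a group: {sorted(unmapped)}")
        missing = set(v.index) - set(self.plot_groups.index)
        if missing:
            raise MetadataError(f"plots without a group label: {sorted(missing)}")
        if not np.issubdtype(v.to_numpy().dtype, np.number):
            raise FormatError("non-numeric function values")

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.indicator_groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def indicators_in(self, group: str) -> list[str]:
        cols = [c for c in self.values.columns if self.indicator_groups[c] == group]
        if not cols:
            raise UsageError(f"unknown or empty function group {group!r}")
        return cols


# ---------------------------------------------------------------------------
# counts / taxonomy / metadata
# ---------------------------------------------------------------------------

def read_otu_table(path, taxonomy_path=None, metadata_path=None) -> OtuTable:
    """Read counts (TSV, taxa rows × sample columns), taxonomy (TSV) and
    sample metadata (CSV) into a validated :class:`OtuTable`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise FormatError("duplicate sample ids in count table header")
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    for col in counts.columns:
        if not pd.api.types.is_numeric_dtype(counts[col]):
            raise FormatError(f"non-numeric counts in sample column {col!r}")
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0, dtype=str)
        taxonomy.index = taxonomy.index.astype(str)
        if taxonomy.index.duplicated().any():
            raise FormatError("duplicate taxon ids in taxonomy table")
    else:
        taxonomy = pd.DataFrame(index=counts.index, columns=RANKS, dtype=object)
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, index_col=0)
        metadata.index = metadata.index.astype(str)
        if metadata.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
    else:
        raise MetadataError("metadata_path is required (every sample needs a group)")
    return OtuTable(counts, taxonomy, metadata)


def write_otu_table(tab: OtuTable, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write counts.tsv / taxonomy.tsv / metadata.csv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / f"{prefix}counts.tsv",
        "taxonomy": out / f"{prefix}taxonomy.tsv",
        "metadata": out / f"{prefix}metadata.csv",
    }
    tab.counts.to_csv(paths["counts"], sep="\t")
    tab.taxonomy.to_csv(paths["taxonomy"], sep="\t")
    tab.metadata.to_csv(paths["metadata"])
    return paths


def read_biom_json(path, metadata_path) -> OtuTable:
    """Read a BIOM v1 JSON table (dense or sparse). Read-only support."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        n_rows, n_cols = doc["shape"]
        row_ids = [r["id"] for r in doc["rows"]]
        col_ids = [c["id"] for c in doc["columns"]]
        mat = np.zeros((n_rows, n_cols))
        if doc.get("matrix_type") == "dense":
            mat[:] = np.asarray(doc["data"], dtype=float)
        else:
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"not a BIOM v1 JSON table: {exc}") from exc
    counts = pd.DataFrame(mat, index=row_ids, columns=col_ids)
    tax_rows = {}
    for r in doc["rows"]:
        lineage = (r.get("metadata") or {}).get("taxonomy")
        if lineage:
            tax_rows[r["id"]] = dict(zip(RANKS, lineage))
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index").reindex(row_ids)
    metadata = pd.read_csv(metadata_path, index_col=0)
    metadata.index = metadata.index.astype(str)
    return OtuTable(counts, taxonomy, metadata)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path) -> skbio.TreeNode:
    """Parse a rooted newick tree; tips must be labeled and unique.

    Missing branch lengths are set to 0 with a logged warning; a malformed
    string raises :class:`FormatError`.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"newick parse error: {exc}") from exc
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if any(n is None or n == "" for n in names):
        raise FormatError("tree has unlabeled tips")
    if len(set(names)) != len(names):
        raise FormatError("duplicate tip labels in tree")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        log.warning("%d branches had no length; set to 0", n_missing)
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# function matrix
# ---------------------------------------------------------------------------

def read_function_matrix(values_path, groups_path, plot_metadata_path=None) -> FunctionMatrix:
    """values CSV (plot rows × indicator columns, optional 'group' column)
    plus an indicator,group CSV."""
    values = pd.read_csv(values_path, index_col=0)
    values.index = values.index.astype(str)
    groups_df = pd.read_csv(groups_path)
    if not {"indicator", "group"} <= set(groups_df.columns):
        raise FormatError("groups file needs 'indicator' and 'group' columns")
    indicator_groups = dict(zip(groups_df["indicator"].astype(str), groups_df["group"].astype(str)))
    if plot_metadata_path is not None:
        meta = pd.read_csv(plot_metadata_path, index_col=0)
        meta.index = meta.index.astype(str)
        plot_groups = meta["group"]
    elif "group" in values.columns:
        plot_groups = values.pop("group").astype(str)
    else:
        raise MetadataError("no plot group labels (metadata file or 'group' column)")
    return FunctionMatrix(values.astype(float), indicator_groups, plot_groups)


def write_function_matrix(fm: FunctionMatrix, out_dir, prefix: str = "") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values = fm.values.copy()
    values.insert(0, "group", fm.plot_groups.loc[values.index].to_numpy())
    paths = {
        "values": out / f"{prefix}functions.csv",
        "groups": out / f"{prefix}function_groups.csv",
    }
    values.to_csv(paths["values"])
    pd.DataFrame(
        {"indicator": list(fm.indicator_groups), "group": list(fm.indicator_groups.values())}
    ).to_csv(paths["groups"], index=False)
    return paths


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(net, path, format: str = "graphml") -> None:
    """Export a co-occurrence network for standard graph tools.

    Nodes carry taxon name, phylum and degree; edges carry the correlation,
    its sign (+1/-1) and weight = |correlation|.
    """
    graph = net.graph if hasattr(net, "graph") else net
    g = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        g.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
        g.nodes[node]["degree"] = graph.degree(node)
    for u, v, attrs in graph.edges(data=True):
        g.add_edge(u, v, **attrs)
    if format == "graphml":
        nx.write_graphml(g, str(path))
    elif format == "gexf":
        nx.write_gexf(g, str(path))
    else:
        raise UsageError(f"unsupported network format {format!r} (graphml|gexf)")


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(str(path))
    if format == "gexf":
        return nx.read_gexf(str(path))
    raise UsageError(f"unsupported network format {format!r} (graphml|gexf)")
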