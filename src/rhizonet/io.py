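"""Readers and writers for the pipeline's on-disk formats.

Community tables are TSV with taxa as rows and samples as columns (header
row of sample IDs); orientation is auto-detected on read by overlap with the
metadata's sample IDs. Sample frames are CSV indexed by sample ID, trees are
Newick, distance matrices are square TSV, networks are edge-list TSV and
GraphML.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import ValidationError
from .network import CoNetwork
from .types import CommunityTable, validate_sample_frame

log = logging.getLogger("rhizonet")


def write_community_tsv(table: CommunityTable, path) -> None:
    """Write taxa (rows) x samples (columns) TSV."""
    table.counts.T.to_csv(path, sep="\t", index_label="taxon_id")


def read_community_tsv(path, sample_ids=None) -> CommunityTable:
    """Read a community TSV, auto-detecting orientation.

    If ``sample_ids`` is given, the axis with the greater ID overlap is
    treated as samples; otherwise taxa-as-rows (the written form) is assumed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    if sample_ids is not None:
        ids = set(map(str, sample_ids))
        col_overlap = len(ids & set(df.columns))
        row_overlap = len(ids & set(df.index))
        if col_overlap == row_overlap == 0:
            raise ValidationError("no overlap between file IDs and expected sample IDs")
        if row_overlap > col_overlap:
            log.info("community table read as samples-in-rows (orientation auto-detected)")
            return CommunityTable(df)
        log.info("community table read as samples-in-columns (orientation auto-detected)")
    return CommunityTable(df.T)


def write_sample_frame(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index_label="sample_id")


def read_sample_frame(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="sample_id")
    frame.index = frame.index.astype(str)
    frame.index.name = None
    return validate_sample_frame(frame)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_tree(path) -> TreeNode:
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValidationError(f"unparseable Newick file {path}: {exc}") from exc


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_network(net: CoNetwork, edge_path, graphml_path=None) -> None:
    """Edge-list TSV (taxon_a, taxon_b, rho, sign) and optional GraphML."""
    rows = [
        {"taxon_a": a, "taxon_b": b, "rho": d["rho"], "sign": d["sign"]}
        for a, b, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "sign"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)


def read_inputs(
    table_path, metadata_path, tree_path=None
) -> tuple[CommunityTable, pd.DataFrame, TreeNode | None]:
    """Load and cross-validate a community table, metadata and optional tree.

    Fails with an explicit list of offending sample IDs on any mismatch, and
    with a missing-taxon error if the tree lacks observed taxa.
    """
    for p in (table_path, metadata_path) + ((tree_path,) if tree_path else ()):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    frame = read_sample_frame(metadata_path)
    table = read_community_tsv(table_path, sample_ids=frame.index)
    validate_sample_frame(frame, table)
    tree = read_tree(tree_path) if tree_path else None
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        observed = set(table.drop_empty_taxa().taxon_ids)
        missing = sorted(observed - tips)
        if missing:
            raise ValidationError(f"tree is missing observed taxa: {missing[:5]}")
    # align metadata row order to the table
    frame = frame.loc[table.sample_ids]
    return table, frame, tree
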