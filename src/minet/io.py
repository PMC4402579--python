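"""Plain-text readers and writers shared across pipeline stages.

All expression matrices travel as TSV with features on rows (first column
= feature ID, header row = sample IDs).  Genomic coordinates are BED6
(0-based half-open).  Interaction files are two-column TSVs; SIF is
accepted for PPI input and produced on export.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples expression matrix.

    The index holds feature IDs, the columns sample IDs; values are floats
    (blank cells become NaN and are handled by preprocessing).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df["chrom"] = df["chrom"].astype(str)
    df["name"] = df["name"].astype(str)
    df[["start", "end"]] = df[["start", "end"]].astype(int)
    return df


def write_bed(features: pd.DataFrame, path: str | Path) -> None:
    features[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_target_db(path: str | Path) -> pd.DataFrame:
    """Two-column (mirna_name, gene_id) flat file, no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["mirna_name", "gene_id"])
    return df.astype(str)


def write_target_db(records: pd.DataFrame, path: str | Path) -> None:
    records[["mirna_name", "gene_id"]].to_csv(path, sep="\t", header=False, index=False)


def read_ppi(path: str | Path) -> nx.Graph:
    """Read a PPI edge list: 2-column TSV or 3-column SIF (a relation b).

    Self-loops and duplicate edges are dropped on read so the returned
    graph always satisfies the network invariants.
    """
    graph = nx.Graph()
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if len(parts) >= 3:  # SIF: source relation target
                a, b = parts[0], parts[2]
            else:
                a, b = parts[0], parts[1]
            if a != b:
                graph.add_edge(a, b)
    return graph


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            handle.write(f"{a}\t{b}\n")


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def write_id_list(ids: list[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for item in ids:
            handle.write(f"{item}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path: str | Path):
    with open(path) as handle:
        return json.load(handle)
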