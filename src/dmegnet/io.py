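"""Readers and writers for the plain-text formats the pipeline exchanges.

All tabular formats are TSV. Matrices are feature x sample with the feature
id in the first column and sample ids in the header. Gene sets use the GMT
convention (name, description, members...). Networks are two-column edge
lists with an optional third numeric score column.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_edge_list",
    "write_edge_list",
    "read_drug_targets",
    "write_drug_targets",
    "read_survival",
    "write_survival",
    "read_groups",
    "read_gmt",
    "write_gmt",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate feature ids in {path}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation TSV with columns (probe, gene, region)."""
    ann = pd.read_csv(path, sep="\t")
    expected = {"probe", "gene", "region"}
    if not expected.issubset(ann.columns):
        raise ValueError(f"probe annotation needs columns {sorted(expected)}")
    return ann[["probe", "gene", "region"]]


def write_probe_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, min_score: float | None = None) -> nx.Graph:
    """Read an undirected edge-list TSV into a simple graph.

    A third column, when present, is an interaction confidence score;
    ``min_score`` keeps only edges with score >= min_score (e.g. 400 for
    a STRING-style network). Self-loops are dropped.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list needs at least two columns")
    if min_score is not None:
        if df.shape[1] < 3:
            raise ValueError("min_score given but edge list has no score column")
        df = df[pd.to_numeric(df[2]) >= min_score]
    graph = nx.Graph()
    graph.add_edges_from(zip(df[0], df[1]))
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_drug_targets(path: str | Path) -> dict[str, set[str]]:
    """Read a (drug, target) TSV into drug -> target gene set."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out: dict[str, set[str]] = {}
    for drug, target in zip(df[0], df[1]):
        out.setdefault(drug, set()).add(target)
    return out


def write_drug_targets(drugs: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(drugs):
            for target in sorted(drugs[drug]):
                fh.write(f"{drug}\t{target}\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV with columns (sample, time, event)."""
    df = pd.read_csv(path, sep="\t")
    expected = {"sample", "time", "event"}
    if not expected.issubset(df.columns):
        raise ValueError(f"survival table needs columns {sorted(expected)}")
    df = df.set_index("sample")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return df[["time", "event"]]


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample")


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column (sample, label) TSV into a sample -> label Series."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return pd.Series(df[1].values, index=df[0].values, name="label")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            members = {g for g in fields[2:] if g}
            if members:
                sets[name] = members
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
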