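"""Reading, writing and preprocessing of omics matrices, marker maps and networks.

File conventions
----------------
* Matrices: delimited text (tab or comma, auto-detected), header row of
  feature names, first column of sample IDs.
* Marker maps: columns ``marker``, ``chromosome``, ``position``.
* Networks: 3-column edge list (``node_i``, ``node_j``, ``weight``), full
  labelled square matrix, or GraphML.

Preprocessing mirrors the standard treatment of designed multi-group omics
experiments: log-transform concentrations, then remove group (e.g.
developmental-stage) mean levels per feature so that downstream covariance
estimation sees within-group variation only.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import IntensityMatrix, MarkerMap, OmicsMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_marker_map",
    "write_marker_map",
    "preprocess",
    "top_variance_filter",
    "read_network",
    "write_network",
]

NETWORK_FORMATS = ("edge-list", "square-matrix", "graphml")


def _detect_delimiter(path) -> str:
    """Pick tab vs comma from the header line; ties resolve to tab."""
    with open(path) as fh:
        header = fh.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def _read_table(path, delimiter: str | None = None) -> pd.DataFrame:
    delimiter = delimiter or _detect_delimiter(path)
    # pandas silently renames duplicate header names; check the raw header
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split(delimiter)[1:]
    dup = pd.Index(names)
    if dup.has_duplicates:
        raise ValueError(f"duplicate column names in {path}: {dup[dup.duplicated()].unique().tolist()}")
    return pd.read_csv(path, sep=delimiter, index_col=0)


def read_matrix(
    path,
    group_column: str | None = None,
    delimiter: str | None = None,
    impute_missing: bool = False,
) -> OmicsMatrix:
    """Read a samples x features matrix; first column = sample IDs, header = features.

    Parameters
    ----------
    group_column
        Name of a column holding categorical sample-group labels; it is
        removed from the numeric matrix and attached as ``group``.
    impute_missing
        If True, missing cells are replaced by the feature mean instead of
        being rejected. Off by default.
    """
    df = _read_table(path, delimiter)
    group = None
    if group_column is not None:
        if group_column not in df.columns:
            raise ValueError(f"group column {group_column!r} not found in {path}")
        group = df[group_column].astype(str)
        df = df.drop(columns=[group_column])
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        if impute_missing:
            numeric = numeric.fillna(numeric.mean(axis=0))
        else:
            r, c = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at row {numeric.index[r]!r}, column "
                f"{numeric.columns[c]!r} in {path}; pass impute_missing=True to mean-impute"
            )
    return OmicsMatrix(numeric.astype(float), group=group)


def write_matrix(data: OmicsMatrix, path, delimiter: str = "\t") -> None:
    df = data.values
    if data.group is not None:
        df = df.copy()
        df["group"] = data.group
    df.to_csv(path, sep=delimiter, index_label="sample")


def read_marker_map(path, delimiter: str | None = None) -> MarkerMap:
    delimiter = delimiter or _detect_delimiter(path)
    tab = pd.read_csv(path, sep=delimiter)
    return MarkerMap(tab)


def write_marker_map(mmap: MarkerMap, path, delimiter: str = "\t") -> None:
    mmap.table.to_csv(path, sep=delimiter, index=False)


def preprocess(
    data: OmicsMatrix,
    log_transform: bool = False,
    center_by_group: bool = False,
) -> OmicsMatrix:
    """Log-transform and/or remove per-group feature means.

    With ``center_by_group`` and no group labels, all samples are treated as
    a single group (global centering). Log transform is the natural log and
    requires strictly positive values.
    """
    values = data.values.copy()
    if log_transform:
        nonpos = values <= 0
        if nonpos.to_numpy().any():
            cells = [
                (values.index[r], values.columns[c])
                for r, c in np.argwhere(nonpos.to_numpy())[:10]
            ]
            raise ValueError(f"log transform requires positive values; offending cells: {cells}")
        values = np.log(values)
    if center_by_group:
        if data.group is None:
            values = values - values.mean(axis=0)
        else:
            values = values.groupby(data.group).transform(lambda g: g - g.mean())
    return OmicsMatrix(values, group=data.group)


def top_variance_filter(data: OmicsMatrix, fraction: float) -> OmicsMatrix:
    """Keep the ``ceil(fraction * K)`` features with largest sample variance.

    Unbiased (n-1) variance; ties broken toward the earlier column; the
    surviving features keep their original column order.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = data.n_features
    n_keep = math.ceil(fraction * k)
    var = data.values.var(axis=0, ddof=1).to_numpy()
    order = np.argsort(-var, kind="stable")[:n_keep]
    keep = np.sort(order)
    return OmicsMatrix(data.values.iloc[:, keep].copy(), group=data.group)


def write_network(net: IntensityMatrix, path, format: str = "edge-list") -> None:
    """Write a network as edge list, labelled square matrix, or GraphML."""
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    if format == "edge-list":
        net.edges().to_csv(path, sep="\t", index=False)
    elif format == "square-matrix":
        net.weights.to_csv(path, sep="\t", index_label="node")
    else:
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in net.node_ids)
        for _, row in net.edges().iterrows():
            g.add_edge(str(row["node_i"]), str(row["node_j"]), weight=float(row["weight"]))
        nx.write_graphml(g, path)


def read_network(path, format: str | None = None, node_ids=None) -> IntensityMatrix:
    """Read a network written by :func:`write_network`.

    ``format=None`` auto-detects: ``.graphml`` suffix, an
    (node_i, node_j, weight) header, or a labelled square matrix.
    ``node_ids`` supplies the full node set for edge lists (isolated nodes
    are otherwise unrecoverable from the file).
    """
    path = Path(path)
    if format is None:
        if path.suffix == ".graphml":
            format = "graphml"
        else:
            with open(path) as fh:
                header = fh.readline()
            cols = header.replace(",", "\t").rstrip("\n").split("\t")
            format = "edge-list" if cols[:3] == ["node_i", "node_j", "weight"] else "square-matrix"
    if format == "square-matrix":
        df = _read_table(path)
        df.columns = df.columns.astype(str)
        df.index = df.index.astype(str)
        return IntensityMatrix(df)
    if format == "edge-list":
        edges = pd.read_csv(path, sep=_detect_delimiter(path))
        nodes = list(map(str, node_ids)) if node_ids is not None else sorted(
            set(edges["node_i"].astype(str)) | set(edges["node_j"].astype(str))
        )
        net = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for _, row in edges.iterrows():
            i, j = str(row["node_i"]), str(row["node_j"])
            net.loc[i, j] = net.loc[j, i] = float(row["weight"])
        return IntensityMatrix(net)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = list(map(str, node_ids)) if node_ids is not None else sorted(g.nodes)
        net = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for i, j, d in g.edges(data=True):
            net.loc[str(i), str(j)] = net.loc[str(j), str(i)] = float(d.get("weight", 1.0))
        return IntensityMatrix(net)
    raise ValueError(f"unknown network format {format!r}")
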