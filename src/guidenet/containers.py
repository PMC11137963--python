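"""Core data containers: omics matrices, marker maps and intensity matrices.

An undirected network over K molecular features is encoded as a symmetric
non-negative K x K weight matrix with zero diagonal (the *intensity matrix*).
Entries are association intensities -- here typically absolute entries of an
estimated precision matrix -- and a zero entry means "no edge".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsMatrix", "MarkerMap", "IntensityMatrix"]

#: entries with absolute value below this are treated as structural zeros
EDGE_TOL = 1e-10


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup}")


@dataclass
class OmicsMatrix:
    """Samples x features numeric matrix with labels and optional sample groups.

    Parameters
    ----------
    values
        DataFrame of shape (n_samples, n_features); index holds sample IDs,
        columns hold feature IDs.
    group
        Optional categorical labels per sample (e.g. developmental stage),
        aligned with ``values.index``.
    """

    values: pd.DataFrame
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.columns, "feature ids")
        _check_unique(self.values.index, "sample ids")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if self.group is not None:
            self.group = pd.Series(self.group)
            if len(self.group) != self.values.shape[0]:
                raise ValueError("group labels do not match number of samples")
            self.group.index = self.values.index

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_features(self, features) -> "OmicsMatrix":
        return OmicsMatrix(self.values.loc[:, list(features)].copy(), group=self.group)


@dataclass
class MarkerMap:
    """Ordered genetic/physical marker positions along chromosomes.

    ``table`` has columns ``marker``, ``chromosome``, ``position``; within each
    chromosome markers are sorted by ascending position. Chromosomes keep
    their order of first appearance.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "position"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"marker map missing columns: {sorted(missing)}")
        _check_unique(self.table["marker"], "marker ids")
        if (self.table["position"].astype(float) < 0).any():
            raise ValueError("marker positions must be >= 0")
        chrom_order = {c: i for i, c in enumerate(self.table["chromosome"].drop_duplicates())}
        tab = self.table.assign(_c=self.table["chromosome"].map(chrom_order))
        tab = tab.sort_values(["_c", "position"], kind="stable").drop(columns="_c")
        self.table = tab.reset_index(drop=True)

    @property
    def marker_ids(self) -> list:
        return list(self.table["marker"])

    @property
    def chromosomes(self) -> list:
        return list(self.table["chromosome"].drop_duplicates())

    def chromosome_table(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]


@dataclass
class IntensityMatrix:
    """Symmetric non-negative weighted adjacency with zero diagonal."""

    weights: pd.DataFrame
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.weights, pd.DataFrame):
            self.weights = pd.DataFrame(self.weights)
        w = self.weights
        if w.shape[0] != w.shape[1]:
            raise ValueError("intensity matrix must be square")
        if not list(w.index) == list(w.columns):
            raise ValueError("row and column labels must match")
        _check_unique(w.columns, "node ids")
        arr = w.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("intensity matrix contains non-finite entries")
        if np.abs(arr - arr.T).max(initial=0.0) > 1e-8:
            raise ValueError("intensity matrix must be symmetric")
        if arr.min(initial=0.0) < -EDGE_TOL:
            raise ValueError("intensity matrix entries must be non-negative")
        arr = np.clip((arr + arr.T) / 2.0, 0.0, None)
        np.fill_diagonal(arr, 0.0)
        arr[arr < EDGE_TOL] = 0.0
        self.weights = pd.DataFrame(arr, index=w.index, columns=w.columns)
        self._validated = True

    @property
    def node_ids(self) -> list:
        return list(self.weights.columns)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def to_numpy(self) -> np.ndarray:
        return self.weights.to_numpy(dtype=float)

    def edges(self) -> pd.DataFrame:
        """Edge list (node_i, node_j, weight) with i < j in label order, weight > 0."""
        arr = self.to_numpy()
        nodes = self.node_ids
        iu, ju = np.triu_indices(len(nodes), k=1)
        mask = arr[iu, ju] > 0
        return pd.DataFrame(
            {
                "node_i": [nodes[i] for i in iu[mask]],
                "node_j": [nodes[j] for j in ju[mask]],
                "weight": arr[iu, ju][mask],
            }
        )

    def edge_set(self) -> set[tuple]:
        e = self.edges()
        return {(i, j) for i, j in zip(e["node_i"], e["node_j"])}

    @property
    def n_edges(self) -> int:
        arr = self.to_numpy()
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return int((arr[iu, ju] > 0).sum())

    @classmethod
    def empty(cls, node_ids) -> "IntensityMatrix":
        k = len(node_ids)
        return cls(pd.DataFrame(np.zeros((k, k)), index=node_ids, columns=node_ids))
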