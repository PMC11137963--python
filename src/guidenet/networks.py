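"""Step 3 — target network reconstruction and network comparison.

The target network is estimated by graphical lasso + StARS on the *fitted*
target values from Step 2, so it reflects only the part of target variation
explained by the guiding layer. For a fair contrast, the unguided network
(graphical lasso on the raw target data) is re-estimated at matched sparsity
— the penalty whose edge count is closest to the guided network's. The
comparison classifies every edge as common or unique to one network, with
per-node gained/lost/retained counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, MarkerMap, OmicsMatrix
from .guiding import (
    EdgeUncertainty,
    StarsSelection,
    default_lambda_grid,
    edge_uncertainty,
    graphical_lasso,
    intensity_from_precision,
    sample_covariance,
    stars_select,
    strength,
)
from .ncr import NcrFit

__all__ = [
    "TargetNetworkResult",
    "NetworkComparison",
    "reconstruct_target",
    "sparsity_match",
    "network_sparsity",
    "compare_networks",
    "hub_nodes",
    "export_multigraph",
]


@dataclass
class TargetNetworkResult:
    """Guided target network with its penalty selection and edge uncertainty."""

    network: IntensityMatrix
    stars: StarsSelection
    uncertainty: EdgeUncertainty
    dropped_features: list


@dataclass
class NetworkComparison:
    """Edge-level difference between two networks on the same node set.

    ``edges`` has one row per edge of either network with columns
    node_i, node_j, class (common / unique_a / unique_b), weight_a,
    weight_b, abs_diff. ``node_summary`` counts, per node, edges unique to
    a (gained by a), unique to b (lost from b's perspective) and common
    (retained).
    """

    edges: pd.DataFrame
    node_summary: pd.DataFrame

    @property
    def common_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["class"] == "common"].reset_index(drop=True)

    @property
    def unique_to_a(self) -> pd.DataFrame:
        return self.edges[self.edges["class"] == "unique_a"].reset_index(drop=True)

    @property
    def unique_to_b(self) -> pd.DataFrame:
        return self.edges[self.edges["class"] == "unique_b"].reset_index(drop=True)


def reconstruct_target(
    fitted: OmicsMatrix,
    stars_kwargs: dict | None = None,
    uncertainty_subsamples: int = 20,
    seed: int = 0,
) -> TargetNetworkResult:
    """Reconstruct the target network from fitted values.

    Zero-variance columns (responses whose selected NCR model was all-zero)
    are excluded before covariance estimation and reported in
    ``dropped_features``; they re-enter the final network as isolated nodes.
    """
    var = fitted.values.var(axis=0, ddof=1)
    keep = [f for f, v in var.items() if v > 1e-14]
    dropped = [f for f in fitted.feature_ids if f not in set(keep)]
    if len(keep) < 3:
        raise ValueError(
            f"only {len(keep)} non-constant fitted columns; no meaningful network"
        )
    sub = fitted.subset_features(keep)
    stars = stars_select(sub, seed=seed, **(stars_kwargs or {}))
    S = sample_covariance(sub, standardize=True)
    fit = graphical_lasso(S, stars.selected_lambda, strict=False)
    net_sub = intensity_from_precision(fit)
    unc_sub = edge_uncertainty(
        sub,
        stars.selected_lambda,
        subsample_count=uncertainty_subsamples,
        subsample_size=stars.subsample_size,
        seed=seed + 1,
    )
    # re-embed dropped responses as isolated nodes
    nodes = fitted.feature_ids
    w = pd.DataFrame(0.0, index=nodes, columns=nodes)
    w.loc[keep, keep] = net_sub.weights
    sd = pd.DataFrame(0.0, index=nodes, columns=nodes)
    sd.loc[keep, keep] = unc_sub.sd
    return TargetNetworkResult(
        network=IntensityMatrix(w),
        stars=stars,
        uncertainty=EdgeUncertainty(
            sd=sd, lam=unc_sub.lam, n_used=unc_sub.n_used, n_skipped=unc_sub.n_skipped
        ),
        dropped_features=dropped,
    )


def sparsity_match(
    data: OmicsMatrix,
    target_edge_count: int,
    lambda_grid: np.ndarray | None = None,
    standardize: bool = True,
) -> tuple[float, IntensityMatrix, int]:
    """Penalty whose graphical-lasso edge count is closest to a target count.

    Graphical-lasso paths rarely hit an exact edge count, so the closest
    achievable count on the grid is used; ties go to the larger penalty
    (the sparser network). Returns (lambda, network, achieved count).
    """
    if target_edge_count < 0:
        raise ValueError("target edge count must be >= 0")
    S = sample_covariance(data, standardize=standardize)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(S)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    best = None  # (|count - target|, lam, net, count); first win at ties = larger lam
    for lam in lambda_grid:
        net = intensity_from_precision(graphical_lasso(S, lam, strict=False))
        count = net.n_edges
        gap = abs(count - target_edge_count)
        if best is None or gap < best[0]:
            best = (gap, float(lam), net, count)
    return best[1], best[2], best[3]


def network_sparsity(net: IntensityMatrix) -> tuple[int, int, float]:
    """(edge_count, possible_edges, sparsity) with possible = K(K-1)/2."""
    k = net.n_nodes
    if k < 2:
        raise ValueError("need at least 2 nodes")
    possible = k * (k - 1) // 2
    count = net.n_edges
    return count, possible, count / possible


def compare_networks(a: IntensityMatrix, b: IntensityMatrix) -> NetworkComparison:
    """Classify edges as common / unique to a / unique to b, with intensity
    differences and per-node gained (unique_a), lost (unique_b) and retained
    (common) counts."""
    if list(a.node_ids) != list(b.node_ids):
        only_a = set(a.node_ids) - set(b.node_ids)
        only_b = set(b.node_ids) - set(a.node_ids)
        raise ValueError(f"node sets differ (only in a: {sorted(only_a)[:5]}, only in b: {sorted(only_b)[:5]})")
    ea, eb = a.edge_set(), b.edge_set()
    wa, wb = a.weights, b.weights
    rows = []
    for i, j in sorted(ea | eb, key=str):
        in_a, in_b = (i, j) in ea, (i, j) in eb
        cls = "common" if in_a and in_b else ("unique_a" if in_a else "unique_b")
        va, vb = float(wa.loc[i, j]), float(wb.loc[i, j])
        rows.append(
            {
                "node_i": i,
                "node_j": j,
                "class": cls,
                "weight_a": va,
                "weight_b": vb,
                "abs_diff": abs(va - vb),
            }
        )
    edges = pd.DataFrame(
        rows, columns=["node_i", "node_j", "class", "weight_a", "weight_b", "abs_diff"]
    )
    counts = pd.DataFrame(
        0, index=a.node_ids, columns=["gained", "lost", "retained"], dtype=int
    )
    label = {"unique_a": "gained", "unique_b": "lost", "common": "retained"}
    for _, row in edges.iterrows():
        col = label[row["class"]]
        counts.loc[row["node_i"], col] += 1
        counts.loc[row["node_j"], col] += 1
    return NetworkComparison(edges=edges, node_summary=counts)


def hub_nodes(net: IntensityMatrix, top_k: int | None = None) -> pd.DataFrame:
    """Nodes ranked by degree; ties broken by strength, then label."""
    arr = net.to_numpy()
    degree = (arr > 0).sum(axis=1)
    s = strength(net)
    tab = pd.DataFrame(
        {"node": net.node_ids, "degree": degree, "strength": s.to_numpy()}
    )
    tab = tab.sort_values(
        ["degree", "strength", "node"],
        ascending=[False, False, True],
        key=lambda c: c.astype(str) if c.name == "node" else c,
        kind="stable",
    ).reset_index(drop=True)
    return tab.head(top_k) if top_k is not None else tab


def export_multigraph(
    target_net: IntensityMatrix, fit: NcrFit, mmap: MarkerMap, path
) -> None:
    """Write the combined target–target / target–marker edge list.

    Target–target rows carry the network intensity; target–marker rows carry
    the (non-zero) NCR coefficient, connecting each response to the mapped
    guiding markers that predict it. Layer labels make the file loadable as
    a multigraph in standard viewers.
    """
    mapped = set(mmap.marker_ids)
    unmapped = [f for f in fit.coefficients.index if f not in mapped]
    if unmapped:
        raise ValueError(f"unmapped guiding features: {unmapped[:10]}")
    rows = []
    for _, e in target_net.edges().iterrows():
        rows.append(
            {
                "layer": "target-target",
                "node_i": e["node_i"],
                "node_j": e["node_j"],
                "weight": e["weight"],
            }
        )
    for resp in fit.response_ids:
        beta = fit.coefficients[resp]
        for marker, coef in beta[beta != 0].items():
            rows.append(
                {"layer": "target-marker", "node_i": resp, "node_j": marker, "weight": coef}
            )
    pd.DataFrame(rows, columns=["layer", "node_i", "node_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )
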