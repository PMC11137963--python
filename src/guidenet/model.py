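"""Guided network estimation as a model object.

`GuidedNetworkModel` holds the target data, the guiding data and the guiding
network (estimated by graphical lasso + StARS, derived from a marker map, or
supplied precomputed). `fit()` runs the three-step procedure —

1. guiding intensity matrix W(X);
2. network-constrained regression of every target on all guiding variables,
   penalties chosen by cross-validation;
3. graphical lasso + StARS on the fitted target values —

plus the unguided baseline network at matched sparsity and the edge-level
comparison, and returns a `GuidedNetworkResults` with the selected
penalties, networks, edge uncertainties and a text `summary()`.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .containers import IntensityMatrix, MarkerMap, OmicsMatrix
from .guiding import (
    EdgeUncertainty,
    StarsSelection,
    edge_uncertainty,
    glasso_network,
    linear_map_network,
)
from .io import read_marker_map, read_matrix, read_network, write_matrix, write_network
from .ncr import NcrFit, build_laplacian, ncr_cv
from .networks import (
    NetworkComparison,
    TargetNetworkResult,
    compare_networks,
    hub_nodes,
    network_sparsity,
    reconstruct_target,
    sparsity_match,
)

__all__ = ["GuidedNetworkModel", "GuidedNetworkResults"]


class GuidedNetworkModel:
    """Three-step guided network estimation.

    Parameters
    ----------
    target
        N x P matrix whose network is to be reconstructed (e.g. metabolites).
    guiding
        N x Q upstream matrix (e.g. SNP genotypes or gene expression), same
        samples in the same order.
    guiding_network
        Optional precomputed Q x Q intensity matrix. If absent, it is built
        from ``marker_map`` (linear chain network) when given, otherwise
        estimated from ``guiding`` by graphical lasso + StARS at fit time.
    marker_map
        Optional marker positions for the guiding features.
    """

    def __init__(
        self,
        target: OmicsMatrix,
        guiding: OmicsMatrix,
        guiding_network: IntensityMatrix | None = None,
        marker_map: MarkerMap | None = None,
    ):
        if list(target.sample_ids) != list(guiding.sample_ids):
            mism = [
                (a, b)
                for a, b in zip(target.sample_ids, guiding.sample_ids)
                if a != b
            ][:5]
            raise ValueError(f"sample IDs misaligned between target and guiding: {mism}")
        if guiding_network is not None and list(guiding_network.node_ids) != list(
            guiding.feature_ids
        ):
            raise ValueError("guiding network nodes do not match guiding features")
        if marker_map is not None:
            missing = set(guiding.feature_ids) - set(marker_map.marker_ids)
            if missing:
                raise ValueError(f"guiding features missing from marker map: {sorted(missing)[:5]}")
        self.target = target
        self.guiding = guiding
        self.guiding_network = guiding_network
        self.marker_map = marker_map

    @classmethod
    def from_files(
        cls,
        target_path,
        guiding_path,
        network_path=None,
        map_path=None,
        group_column: str | None = None,
    ) -> "GuidedNetworkModel":
        target = read_matrix(target_path, group_column=group_column)
        guiding = read_matrix(guiding_path, group_column=group_column)
        net = None
        mmap = read_marker_map(map_path) if map_path else None
        if network_path:
            net = read_network(network_path, node_ids=guiding.feature_ids)
        return cls(target, guiding, guiding_network=net, marker_map=mmap)

    def fit(
        self,
        seed: int = 0,
        folds: int = 5,
        lambda1_grid=None,
        lambda2_grid=None,
        stars_kwargs: dict | None = None,
        uncertainty_subsamples: int = 20,
        baseline: bool = True,
        shared_penalties: bool = False,
    ) -> "GuidedNetworkResults":
        stars_kwargs = dict(stars_kwargs or {})
        guiding_stars = None
        if self.guiding_network is not None:
            w_guide = self.guiding_network
            guide_source = "precomputed"
        elif self.marker_map is not None:
            w_guide = linear_map_network(self.marker_map)
            # align node order with the guiding feature order
            w_guide = IntensityMatrix(
                w_guide.weights.loc[self.guiding.feature_ids, self.guiding.feature_ids]
            )
            guide_source = "marker-map"
        else:
            w_guide, _, guiding_stars = glasso_network(
                self.guiding, stars_kwargs=stars_kwargs, seed=seed
            )
            guide_source = "glasso-stars"

        lap = build_laplacian(w_guide)
        ncr_fit = ncr_cv(
            self.guiding,
            self.target,
            lap,
            lambda1_grid=lambda1_grid,
            lambda2_grid=lambda2_grid,
            folds=folds,
            seed=seed,
            shared_penalties=shared_penalties,
        )
        fitted = OmicsMatrix(ncr_fit.fitted.copy(), group=self.target.group)
        target_res = reconstruct_target(
            fitted,
            stars_kwargs=stars_kwargs,
            uncertainty_subsamples=uncertainty_subsamples,
            seed=seed + 10,
        )

        baseline_net = None
        baseline_lambda = None
        baseline_unc = None
        comparison = None
        if baseline:
            baseline_lambda, baseline_net, _ = sparsity_match(
                self.target, target_res.network.n_edges
            )
            baseline_unc = edge_uncertainty(
                self.target,
                baseline_lambda,
                subsample_count=uncertainty_subsamples,
                subsample_size=target_res.stars.subsample_size,
                seed=seed + 11,
            )
            comparison = compare_networks(target_res.network, baseline_net)

        manifest = {
            "package_version": __version__,
            "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
            "seed": seed,
            "folds": folds,
            "guiding_source": guide_source,
            "n_samples": self.target.n_samples,
            "n_target": self.target.n_features,
            "n_guiding": self.guiding.n_features,
            "guiding_lambda": guiding_stars.selected_lambda if guiding_stars else None,
            "target_lambda": target_res.stars.selected_lambda,
            "baseline_lambda": baseline_lambda,
            "guided_edges": target_res.network.n_edges,
            "baseline_edges": baseline_net.n_edges if baseline_net else None,
            "zero_responses": ncr_fit.zero_responses,
            "penalties": {
                r: {"lambda1": p.lambda1, "lambda2": p.lambda2}
                for r, p in ncr_fit.penalties.items()
            },
            "stars": {
                "subsample_count": target_res.stars.subsample_count,
                "subsample_size": target_res.stars.subsample_size,
                "threshold": target_res.stars.threshold,
            },
        }
        return GuidedNetworkResults(
            model=self,
            guiding_network=w_guide,
            guiding_stars=guiding_stars,
            ncr=ncr_fit,
            fitted=fitted,
            target=target_res,
            baseline_network=baseline_net,
            baseline_lambda=baseline_lambda,
            baseline_uncertainty=baseline_unc,
            comparison=comparison,
            manifest=manifest,
        )


@dataclass
class GuidedNetworkResults:
    """Everything the three-step fit produced."""

    model: GuidedNetworkModel
    guiding_network: IntensityMatrix
    guiding_stars: StarsSelection | None
    ncr: NcrFit
    fitted: OmicsMatrix
    target: TargetNetworkResult
    baseline_network: IntensityMatrix | None
    baseline_lambda: float | None
    baseline_uncertainty: EdgeUncertainty | None
    comparison: NetworkComparison | None
    manifest: dict

    @property
    def target_network(self) -> IntensityMatrix:
        return self.target.network

    def summary(self) -> str:
        count, possible, spars = network_sparsity(self.target_network)
        lines = [
            "Guided network estimation",
            "=" * 60,
            f"samples: {self.model.target.n_samples}   targets: {self.model.target.n_features}"
            f"   guiding: {self.model.guiding.n_features}",
            f"guiding network source: {self.manifest['guiding_source']}"
            + (
                f" (lambda = {self.manifest['guiding_lambda']:.4g})"
                if self.manifest["guiding_lambda"]
                else ""
            ),
            f"target network: lambda = {self.target.stars.selected_lambda:.4g}, "
            f"{count} of {possible} possible edges (sparsity {spars:.4g})",
        ]
        if self.baseline_network is not None:
            bcount, _, bspars = network_sparsity(self.baseline_network)
            lines.append(
                f"unguided baseline: lambda = {self.baseline_lambda:.4g}, "
                f"{bcount} edges (sparsity {bspars:.4g}, matched)"
            )
            mean_sd_guided = self.target.uncertainty.mean_edge_sd(self.target_network.edge_set())
            mean_sd_base = self.baseline_uncertainty.mean_edge_sd(
                self.baseline_network.edge_set()
            )
            lines.append(
                f"mean edge SD: guided {mean_sd_guided:.4g} vs unguided {mean_sd_base:.4g}"
            )
            cls = self.comparison.edges["class"].value_counts()
            lines.append(
                f"edges: common {cls.get('common', 0)}, unique to guided "
                f"{cls.get('unique_a', 0)}, unique to unguided {cls.get('unique_b', 0)}"
            )
        if self.ncr.zero_responses:
            lines.append(f"all-zero responses (isolated nodes): {self.ncr.zero_responses}")
        hubs = hub_nodes(self.target_network, top_k=5)
        lines.append(
            "top hubs (degree): "
            + ", ".join(f"{r.node} ({r.degree})" for r in hubs.itertuples())
        )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write networks, coefficients, fitted values, comparison and manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_network(self.guiding_network, outdir / "guiding_network.tsv", "edge-list")
        write_network(self.target_network, outdir / "target_network.tsv", "square-matrix")
        self.ncr.coefficients.to_csv(outdir / "coefficients.tsv", sep="\t", index_label="predictor")
        write_matrix(self.fitted, outdir / "fitted.tsv")
        self.target.uncertainty.sd.to_csv(outdir / "target_edge_sd.tsv", sep="\t", index_label="node")
        if self.baseline_network is not None:
            write_network(self.baseline_network, outdir / "unguided_network.tsv", "square-matrix")
            self.comparison.edges.to_csv(outdir / "comparison.tsv", sep="\t", index=False)
            self.comparison.node_summary.to_csv(
                outdir / "node_changes.tsv", sep="\t", index_label="node"
            )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
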