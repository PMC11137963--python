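"""Step 1 — the guiding network.

Two routes produce the guiding intensity matrix W(X):

* **Estimated**: an L1-penalized Gaussian graphical model (graphical lasso)
  whose penalty is chosen by StARS (Stability Approach to Regularization
  Selection): the least regularization whose edge set stays stable under
  random subsampling. The intensity matrix is the absolute off-diagonal of
  the estimated precision matrix.
* **Known a priori**: for ordered genetic markers, a linear chain network in
  which consecutive markers on a chromosome are connected with weight
  ``1 - (pos_j - pos_i) / chromosome_span`` and markers on different
  chromosomes are never connected.

Also here: node strength (row sums of W) and edge-wise uncertainty (the SD
of edge intensities over graphical-lasso refits on subsamples at fixed
penalty), both reused in Step 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_glasso

from .containers import IntensityMatrix, MarkerMap, OmicsMatrix

__all__ = [
    "GlassoResult",
    "StarsSelection",
    "EdgeUncertainty",
    "GlassoConvergenceError",
    "sample_covariance",
    "graphical_lasso",
    "intensity_from_precision",
    "default_lambda_grid",
    "stars_select",
    "glasso_network",
    "linear_map_network",
    "strength",
    "edge_uncertainty",
]

#: |precision| entries below this are treated as absent edges
EDGE_EPS = 1e-8


class GlassoConvergenceError(RuntimeError):
    """Graphical lasso failed to converge; carries the last duality gap."""

    def __init__(self, max_iter: int, gap: float):
        self.gap = gap
        super().__init__(
            f"graphical lasso did not converge in {max_iter} iterations (duality gap {gap:.3e})"
        )


@dataclass
class GlassoResult:
    """Penalized precision estimate, its covariance input and penalty."""

    precision: pd.DataFrame
    covariance_input: pd.DataFrame
    lam: float
    n_iter: int = 0

    @property
    def node_ids(self) -> list:
        return list(self.precision.columns)


@dataclass
class StarsSelection:
    """StARS path summary: per-penalty instability and the selected penalty."""

    lambda_grid: np.ndarray  # descending
    instability: np.ndarray  # raw, aligned with lambda_grid
    monotonized: np.ndarray  # cummax from the sparse (large-lambda) end
    selected_lambda: float
    subsample_count: int
    subsample_size: int
    seed: int
    threshold: float
    threshold_exceeded: bool = False  # no grid point met the threshold


@dataclass
class EdgeUncertainty:
    """Edge-wise standard deviation of |precision| over subsampled refits."""

    sd: pd.DataFrame
    lam: float
    n_used: int
    n_skipped: int = 0

    def mean_edge_sd(self, edges: set | None = None) -> float:
        """Mean SD over the upper triangle, or over a given edge set."""
        arr = self.sd.to_numpy()
        nodes = list(self.sd.columns)
        if edges is None:
            iu, ju = np.triu_indices(len(nodes), k=1)
            return float(arr[iu, ju].mean())
        pos = {n: i for i, n in enumerate(nodes)}
        vals = [arr[pos[i], pos[j]] for i, j in edges]
        return float(np.mean(vals)) if vals else 0.0


def sample_covariance(data: OmicsMatrix, standardize: bool = True) -> pd.DataFrame:
    """Sample covariance (unbiased, n-1) or, with ``standardize``, correlation."""
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples for a covariance")
    arr = data.to_numpy()
    cov = np.cov(arr, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if standardize:
        sd = np.sqrt(np.diag(cov))
        zero = np.flatnonzero(sd <= 0)
        if zero.size:
            names = [data.feature_ids[i] for i in zero]
            raise ValueError(f"zero-variance features cannot be standardized: {names}")
        cov = cov / np.outer(sd, sd)
        np.fill_diagonal(cov, 1.0)
    cov = (cov + cov.T) / 2.0
    return pd.DataFrame(cov, index=data.feature_ids, columns=data.feature_ids)


def graphical_lasso(
    S: pd.DataFrame | np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_iter: int = 500,
    strict: bool = True,
) -> GlassoResult:
    """Estimate a sparse precision matrix by maximizing
    ``log|Theta| - tr(S Theta) - lam * ||Theta||_1`` (off-diagonal penalty).

    ``lam = 0`` returns the plain inverse of S. Off-diagonal entries of the
    estimate below a small tolerance define missing edges. With
    ``strict=False`` non-convergence at ``max_iter`` only warns and the last
    iterate is returned (used inside subsampling loops, where ill-conditioned
    inputs at small penalties are routine and edge sets are already stable).
    """
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    labels = list(S.columns) if isinstance(S, pd.DataFrame) else list(range(np.asarray(S).shape[0]))
    arr = np.asarray(S, dtype=float)
    if np.abs(arr - arr.T).max(initial=0.0) > 1e-8:
        raise ValueError("covariance input must be symmetric")
    if (np.diag(arr) <= 0).any():
        raise ValueError("covariance diagonal must be positive")
    if lam == 0:
        prec = np.linalg.inv(arr)
        n_iter = 0
    else:
        # on ill-conditioned inputs the solver can fail outright; in
        # non-strict mode retry with a small diagonal ridge (shrinkage)
        ridges = [0.0] if strict else [0.0, 1e-3, 0.05]
        mean_diag = float(np.diag(arr).mean())
        last_err: Exception | None = None
        for eps in ridges:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, prec, costs, n_iter = _sk_glasso(
                        arr + eps * mean_diag * np.eye(arr.shape[0]),
                        alpha=lam,
                        tol=tol,
                        max_iter=max_iter,
                        return_costs=True,
                        return_n_iter=True,
                    )
                if eps > 0:
                    warnings.warn(
                        f"graphical lasso needed a diagonal ridge of {eps:g} "
                        "to handle an ill-conditioned covariance",
                        stacklevel=2,
                    )
                last_err = None
                break
            except FloatingPointError as e:
                last_err = e
        if last_err is not None:
            raise GlassoConvergenceError(max_iter, float("nan")) from last_err
        gap = costs[-1][1]
        # the coordinate-descent dual gap stalls slightly above tol on some
        # inputs; only an order-of-magnitude miss counts as non-convergence
        if n_iter >= max_iter and (not np.isfinite(gap) or abs(gap) > 10 * tol):
            if strict:
                raise GlassoConvergenceError(max_iter, float(gap))
            warnings.warn(
                f"graphical lasso stopped at max_iter={max_iter} "
                f"(duality gap {gap:.2e}); using last iterate",
                stacklevel=2,
            )
    prec = (prec + prec.T) / 2.0
    off = ~np.eye(len(labels), dtype=bool)
    prec[off & (np.abs(prec) < EDGE_EPS)] = 0.0
    prec_df = pd.DataFrame(prec, index=labels, columns=labels)
    cov_df = pd.DataFrame(arr, index=labels, columns=labels)
    return GlassoResult(precision=prec_df, covariance_input=cov_df, lam=float(lam), n_iter=n_iter)


def intensity_from_precision(fit: GlassoResult) -> IntensityMatrix:
    """Intensity matrix |Theta_hat| with the diagonal forced to zero."""
    arr = np.abs(fit.precision.to_numpy(dtype=float))
    np.fill_diagonal(arr, 0.0)
    arr[arr < EDGE_EPS] = 0.0
    return IntensityMatrix(pd.DataFrame(arr, index=fit.node_ids, columns=fit.node_ids))


def default_lambda_grid(
    S: pd.DataFrame | np.ndarray, n_points: int = 30, min_ratio: float = 0.01
) -> np.ndarray:
    """Descending log-spaced penalty grid from max|S_ij| (provably empty graph)
    down to ``min_ratio`` times it."""
    arr = np.asarray(S, dtype=float)
    off = arr[~np.eye(arr.shape[0], dtype=bool)]
    lam_max = float(np.abs(off).max()) if off.size else 1.0
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, min_ratio * lam_max, n_points)


def _edge_indicator(prec: np.ndarray) -> np.ndarray:
    k = prec.shape[0]
    iu, ju = np.triu_indices(k, 1)
    return (np.abs(prec[iu, ju]) > EDGE_EPS).astype(float)


def stars_select(
    data: OmicsMatrix,
    lambda_grid: np.ndarray | None = None,
    instability_threshold: float = 0.05,
    subsample_count: int = 20,
    subsample_size: int | None = None,
    seed: int = 0,
    standardize: bool = True,
    tol: float = 1e-4,
    max_iter: int = 200,
    n_lambda: int = 30,
    lambda_min_ratio: float = 0.01,
) -> StarsSelection:
    """Select the graphical-lasso penalty by subsampling stability (StARS).

    For each penalty on a descending grid, networks are estimated on
    ``subsample_count`` random subsamples of size ``subsample_size`` (default
    ``floor(10 * sqrt(N))``, capped at N-1, drawn without replacement). With
    edge selection frequency ``theta`` over subsamples, the per-penalty
    instability is the mean over node pairs of ``2 * theta * (1 - theta)``;
    it is monotonized by a running maximum from the sparse end and the
    smallest penalty whose monotonized instability stays at or below the
    threshold is selected. If none qualifies the sparsest grid point is
    returned with ``threshold_exceeded=True``.
    """
    n = data.n_samples
    if subsample_size is None:
        subsample_size = min(int(np.floor(10 * np.sqrt(n))), n - 1)
    if not 1 < subsample_size < n:
        raise ValueError(f"subsample_size must be in (1, N); got {subsample_size} for N={n}")
    S_full = sample_covariance(data, standardize=standardize)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(S_full, n_points=n_lambda, min_ratio=lambda_min_ratio)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")

    rng = np.random.default_rng(seed)
    arr = data.to_numpy()
    sub_covs = []
    for _ in range(subsample_count):
        idx = rng.choice(n, size=subsample_size, replace=False)
        sub = OmicsMatrix(pd.DataFrame(arr[idx], columns=data.feature_ids))
        sub_covs.append(sample_covariance(sub, standardize=standardize).to_numpy())

    k = data.n_features
    n_pairs = k * (k - 1) // 2
    instability_list: list[float] = []
    running_max = 0.0
    # scan from the sparse (large-penalty) end; once the monotonized
    # instability exceeds the threshold no denser penalty can be selected,
    # so the rest of the grid need not be fit
    for lam in lambda_grid:
        freq = np.zeros(n_pairs)
        used = 0
        for S in sub_covs:
            try:
                fit = graphical_lasso(S, lam, tol=tol, max_iter=max_iter, strict=False)
            except GlassoConvergenceError as e:
                warnings.warn(f"subsample refit failed at lambda={lam:.4g}: {e}", stacklevel=2)
                continue
            freq += _edge_indicator(fit.precision.to_numpy())
            used += 1
        if used < subsample_count / 2:
            raise RuntimeError(
                f"StARS: more than half the subsample refits failed at lambda={lam:.4g}"
            )
        freq /= used
        xi = float((2 * freq * (1 - freq)).mean()) if n_pairs else 0.0
        instability_list.append(xi)
        running_max = max(running_max, xi)
        if running_max > instability_threshold:
            break

    scanned = np.asarray(lambda_grid[: len(instability_list)])
    instability = np.asarray(instability_list)
    monotonized = np.maximum.accumulate(instability)
    ok = np.flatnonzero(monotonized <= instability_threshold)
    if ok.size:
        selected = float(scanned[ok[-1]])  # smallest penalty still stable
        exceeded = False
    else:
        selected = float(scanned[0])
        exceeded = True
        warnings.warn(
            "no penalty on the grid met the StARS instability threshold; "
            "returning the sparsest grid point",
            stacklevel=2,
        )
    return StarsSelection(
        lambda_grid=scanned,
        instability=instability,
        monotonized=monotonized,
        selected_lambda=selected,
        subsample_count=subsample_count,
        subsample_size=subsample_size,
        seed=seed,
        threshold=instability_threshold,
        threshold_exceeded=exceeded,
    )


def glasso_network(
    data: OmicsMatrix,
    lam: float | None = None,
    standardize: bool = True,
    stars_kwargs: dict | None = None,
    seed: int = 0,
) -> tuple[IntensityMatrix, GlassoResult, StarsSelection | None]:
    """Estimate an intensity matrix by graphical lasso, selecting the penalty
    by StARS unless ``lam`` is given."""
    stars = None
    if lam is None:
        stars = stars_select(data, seed=seed, standardize=standardize, **(stars_kwargs or {}))
        lam = stars.selected_lambda
    S = sample_covariance(data, standardize=standardize)
    fit = graphical_lasso(S, lam)
    return intensity_from_precision(fit), fit, stars


def linear_map_network(mmap: MarkerMap) -> IntensityMatrix:
    """Linear chain network from marker proximity.

    Consecutive markers i, j=i+1 on the same chromosome get weight
    ``1 - (pos_j - pos_i) / (pos_last - pos_first)`` (per-chromosome span);
    all other pairs, and all cross-chromosome pairs, get 0. A two-marker
    chromosome forces weight 0 (its only gap equals the span); this is
    reported as a warning.
    """
    markers = mmap.marker_ids
    k = len(markers)
    net = pd.DataFrame(0.0, index=markers, columns=markers)
    for chrom in mmap.chromosomes:
        tab = mmap.chromosome_table(chrom)
        pos = tab["position"].to_numpy(dtype=float)
        ids = list(tab["marker"])
        if len(ids) < 2:
            continue
        span = pos[-1] - pos[0]
        if span <= 0:
            raise ValueError(f"chromosome {chrom!r}: all marker positions equal (zero span)")
        if len(ids) == 2:
            warnings.warn(
                f"chromosome {chrom!r} has only 2 markers; its single link has weight 0",
                stacklevel=2,
            )
        w = 1.0 - np.diff(pos) / span
        for a, b, wij in zip(ids[:-1], ids[1:], w):
            net.loc[a, b] = net.loc[b, a] = wij
    return IntensityMatrix(net)


def strength(net: IntensityMatrix) -> pd.Series:
    """Node strength: total intensity of a node's connections (row sum of W)."""
    return net.weights.sum(axis=1)


def edge_uncertainty(
    data: OmicsMatrix,
    lambda_fixed: float,
    subsample_count: int = 20,
    subsample_size: int | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> EdgeUncertainty:
    """Edge-wise SD of the intensity matrix over subsampled refits at fixed penalty.

    Each of ``subsample_count`` random subsamples is refit with graphical
    lasso at ``lambda_fixed``; the SD of |precision| per node pair across the
    refits quantifies the uncertainty of each edge. Subsamples on which the
    refit fails (e.g. a degenerate covariance) are skipped with a warning;
    more than half failing is an error.
    """
    if lambda_fixed <= 0:
        raise ValueError("lambda_fixed must be positive")
    n = data.n_samples
    if subsample_size is None:
        subsample_size = min(int(np.floor(10 * np.sqrt(n))), n - 1)
    if not 1 < subsample_size < n:
        raise ValueError(f"subsample_size must be in (1, N); got {subsample_size} for N={n}")
    rng = np.random.default_rng(seed)
    arr = data.to_numpy()
    mats, skipped = [], 0
    for _ in range(subsample_count):
        idx = rng.choice(n, size=subsample_size, replace=False)
        try:
            sub = OmicsMatrix(pd.DataFrame(arr[idx], columns=data.feature_ids))
            S = sample_covariance(sub, standardize=standardize)
            fit = graphical_lasso(S, lambda_fixed, strict=False)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError, GlassoConvergenceError) as e:
            skipped += 1
            warnings.warn(f"subsample refit failed and was skipped: {e}", stacklevel=2)
            continue
        w = np.abs(fit.precision.to_numpy())
        np.fill_diagonal(w, 0.0)
        mats.append(w)
    if skipped > subsample_count / 2:
        raise RuntimeError(f"{skipped}/{subsample_count} subsample refits failed")
    stack = np.stack(mats)
    sd = stack.std(axis=0, ddof=0)
    sd = (sd + sd.T) / 2.0
    np.fill_diagonal(sd, 0.0)
    return EdgeUncertainty(
        sd=pd.DataFrame(sd, index=data.feature_ids, columns=data.feature_ids),
        lam=float(lambda_fixed),
        n_used=len(mats),
        n_skipped=skipped,
    )
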