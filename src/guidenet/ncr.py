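"""Step 2 — network-constrained regularized regression (NCR).

Each target variable y_p is regressed on *all* Q guiding variables under

    ||y_p - X b||^2 + lambda1 * ||b||_1
                    + lambda2 * sum_{i~j} W_ij (b_i/sqrt(s_i) - b_j/sqrt(s_j))^2,

where the sum runs over edges of the guiding network W and s_i is the node
strength. The L1 part drops predictors; the smoothness part shrinks the
strength-scaled coefficients of connected predictors toward each other, so
groups of connected predictors enter the model together (the grouping
property the plain LASSO lacks).

The smoothness penalty is the quadratic form b' L b of a strength-normalized
graph Laplacian L, so the whole criterion reduces to a LASSO on augmented
data: stack X with sqrt(lambda2) * L^{1/2} and pad y with Q zeros. The inner
LASSO is solved by coordinate descent (scikit-learn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .containers import IntensityMatrix, MarkerMap, OmicsMatrix

__all__ = [
    "NcrPenalty",
    "NormalizedLaplacian",
    "NcrFit",
    "build_laplacian",
    "network_penalty",
    "ncr_solve",
    "lambda1_max",
    "default_lambda1_grid",
    "default_lambda2_grid",
    "ncr_cv",
    "grouping_check",
    "qtl_regions",
]


@dataclass(frozen=True)
class NcrPenalty:
    """The two NCR penalty weights: L1 (sparsity) and network smoothness."""

    lambda1: float
    lambda2: float

    def __post_init__(self):
        if not (np.isfinite(self.lambda1) and np.isfinite(self.lambda2)):
            raise ValueError("penalties must be finite")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class NormalizedLaplacian:
    """Strength-normalized Laplacian of a guiding network.

    For nodes with positive strength, ``L_ii = 1`` and
    ``L_ij = -W_ij / sqrt(s_i s_j)``; rows/columns of isolated nodes are
    zero, so the penalty ignores them. ``b' L b`` equals the edge sum of
    squared scaled-coefficient differences exactly.
    """

    matrix: pd.DataFrame
    strengths: pd.Series
    _sqrt: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def node_ids(self) -> list:
        return list(self.matrix.columns)

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)

    def sqrt_matrix(self) -> np.ndarray:
        """Symmetric square root by eigendecomposition; negative eigenvalues
        (rounding artefacts — L is PSD analytically) are clipped at 0."""
        if self._sqrt is None:
            vals, vecs = np.linalg.eigh(self.to_numpy())
            vals = np.clip(vals, 0.0, None)
            object.__setattr__(self, "_sqrt", (vecs * np.sqrt(vals)) @ vecs.T)
        return self._sqrt


@dataclass
class NcrFit:
    """Fitted NCR regressions for all P responses.

    ``coefficients`` is Q x P (one column per response, on the original
    predictor scale), ``fitted`` is N x P with
    ``fitted = X @ coefficients + intercept``. Responses whose selected
    model is all-zero are flagged in ``zero_responses``.
    """

    coefficients: pd.DataFrame
    intercepts: pd.Series
    penalties: dict[str, NcrPenalty]
    fitted: pd.DataFrame
    cv_table: pd.DataFrame | None = None
    seed: int | None = None

    @property
    def zero_responses(self) -> list:
        coef = self.coefficients
        return [c for c in coef.columns if (coef[c] == 0).all()]

    @property
    def response_ids(self) -> list:
        return list(self.coefficients.columns)


def build_laplacian(net: IntensityMatrix) -> NormalizedLaplacian:
    """Strength-normalized graph Laplacian of an intensity matrix."""
    w = net.to_numpy()
    if w.min(initial=0.0) < 0:
        raise ValueError("negative edge weight; invalid intensity matrix")
    s = w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sqrt = np.where(s > 0, 1.0 / np.sqrt(np.where(s > 0, s, 1.0)), 0.0)
    lap = -w * np.outer(inv_sqrt, inv_sqrt)
    np.fill_diagonal(lap, np.where(s > 0, 1.0, 0.0))
    lap = (lap + lap.T) / 2.0
    nodes = net.node_ids
    return NormalizedLaplacian(
        matrix=pd.DataFrame(lap, index=nodes, columns=nodes),
        strengths=pd.Series(s, index=nodes),
    )


def network_penalty(beta: np.ndarray, net: IntensityMatrix) -> float:
    """Direct edge-sum form of the smoothness penalty (for checks/reports)."""
    w = net.to_numpy()
    s = w.sum(axis=1)
    beta = np.asarray(beta, dtype=float)
    scaled = np.where(s > 0, beta / np.sqrt(np.where(s > 0, s, 1.0)), 0.0)
    iu, ju = np.triu_indices(len(s), 1)
    return float(np.sum(w[iu, ju] * (scaled[iu] - scaled[ju]) ** 2))


def _as_array(X) -> np.ndarray:
    if isinstance(X, OmicsMatrix):
        return X.to_numpy()
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def ncr_solve(
    X,
    y,
    L: NormalizedLaplacian | None,
    penalty: NcrPenalty,
    tol: float = 1e-9,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Minimize the NCR criterion for one response; returns beta (length Q).

    X is used as given (standardize beforehand if desired) and y should be
    centered. The problem is reduced to a LASSO on data augmented with
    ``sqrt(lambda2) * L^{1/2}`` rows; with ``lambda1 = 0`` the closed-form
    generalized ridge solution ``(X'X + lambda2 L)^{-1} X'y`` is used.
    """
    X = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    n, q = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have different numbers of samples")
    lam1, lam2 = penalty.lambda1, penalty.lambda2
    if lam2 > 0:
        if L is None:
            raise ValueError("lambda2 > 0 requires a Laplacian")
        if L.matrix.shape[0] != q:
            raise ValueError(
                f"Laplacian is over {L.matrix.shape[0]} nodes but X has {q} predictors"
            )
    if lam1 == 0:
        gram = X.T @ X
        if lam2 > 0:
            gram = gram + lam2 * L.to_numpy()
        beta, *_ = np.linalg.lstsq(gram, X.T @ y, rcond=None)
        return beta
    if lam2 > 0:
        X_aug = np.vstack([X, np.sqrt(lam2) * L.sqrt_matrix()])
        y_aug = np.concatenate([y, np.zeros(q)])
    else:
        X_aug, y_aug = X, y
    n_aug = X_aug.shape[0]
    # sklearn minimizes (1/2n)||y-Xb||^2 + alpha||b||_1; our criterion has no 1/n
    import warnings as _warnings

    model = Lasso(
        alpha=lam1 / (2 * n_aug), fit_intercept=False, tol=tol, max_iter=max_iter
    )
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model.fit(X_aug, y_aug)
    # sklearn's stopping rule scales tol by ||y||^2; accept a stall within an
    # order of magnitude of that target
    if model.n_iter_ >= max_iter and model.dual_gap_ > 10 * tol * max(y_aug @ y_aug, 1e-12):
        raise RuntimeError(
            f"NCR coordinate descent did not converge in {max_iter} iterations "
            f"(dual gap {model.dual_gap_:.3e})"
        )
    return model.coef_.astype(float)


def lambda1_max(X, y) -> float:
    """Smallest L1 penalty giving an all-zero solution at lambda2 = 0
    (criterion form without 1/n): 2 * max|X'y|."""
    X = _as_array(X)
    y = np.asarray(y, dtype=float).ravel()
    return float(2 * np.abs(X.T @ y).max())


def default_lambda1_grid(X, Y, n_points: int = 10) -> np.ndarray:
    """Descending log-spaced grid from the largest per-response lambda1_max
    down to 1% of it."""
    X = _as_array(X)
    Yarr = _as_array(Y)
    if Yarr.ndim == 1:
        Yarr = Yarr[:, None]
    lmax = max(lambda1_max(X, Yarr[:, p]) for p in range(Yarr.shape[1]))
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, 0.01 * lmax, n_points)


def default_lambda2_grid(L: NormalizedLaplacian | None) -> np.ndarray:
    """{0, 0.1, 1, 10} scaled by Q / trace(L); collapses to {0} for an
    edgeless network."""
    if L is None:
        return np.array([0.0])
    tr = float(np.trace(L.to_numpy()))
    if tr <= 0:
        return np.array([0.0])
    scale = L.matrix.shape[0] / tr
    return np.array([0.0, 0.1 * scale, 1.0 * scale, 10.0 * scale])


def _standardize_design(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def ncr_cv(
    X: OmicsMatrix,
    Y: OmicsMatrix,
    L: NormalizedLaplacian | None,
    lambda1_grid: np.ndarray | None = None,
    lambda2_grid: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
    shared_penalties: bool = False,
) -> NcrFit:
    """Fit all P responses with (lambda1, lambda2) chosen by K-fold CV.

    The fold split is shared across responses (seeded, deterministic). For
    each response the grid point with minimum mean squared prediction error
    is selected, ties broken toward larger (lambda1, lambda2) — the sparser,
    smoother model. With ``shared_penalties`` one pair minimizing the error
    summed over responses is used for every response. Predictors are
    standardized internally (default) and coefficients returned on the
    original scale; responses are centered per training fold.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if list(X.sample_ids) != list(Y.sample_ids):
        raise ValueError("X and Y must share sample ids in the same order")
    n = X.n_samples
    if n < folds:
        raise ValueError(f"fewer samples ({n}) than folds ({folds})")
    Xarr = X.to_numpy()
    Yarr = Y.to_numpy()
    q, p = X.n_features, Y.n_features
    if standardize:
        Xs, x_mean, x_sd = _standardize_design(Xarr)
    else:
        Xs, x_mean, x_sd = Xarr, np.zeros(q), np.ones(q)
    if lambda1_grid is None:
        lambda1_grid = default_lambda1_grid(Xs, Yarr - Yarr.mean(axis=0))
    if lambda2_grid is None:
        lambda2_grid = default_lambda2_grid(L)
    lambda1_grid = np.sort(np.asarray(lambda1_grid, dtype=float))[::-1]
    lambda2_grid = np.sort(np.asarray(lambda2_grid, dtype=float))[::-1]
    grid = [(l1, l2) for l1 in lambda1_grid for l2 in lambda2_grid]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(Xs))

    cv_err = np.zeros((len(grid), p))
    for train, test in splits:
        y_tr_mean = Yarr[train].mean(axis=0)
        x_tr_mean = Xs[train].mean(axis=0)
        X_tr = Xs[train] - x_tr_mean
        X_te = Xs[test] - x_tr_mean
        for gi, (l1, l2) in enumerate(grid):
            for pi in range(p):
                beta = ncr_solve(
                    X_tr, Yarr[train, pi] - y_tr_mean[pi], L, NcrPenalty(l1, l2)
                )
                pred = X_te @ beta + y_tr_mean[pi]
                cv_err[gi, pi] += np.mean((Yarr[test, pi] - pred) ** 2)
    cv_err /= len(splits)

    def _pick(errors: np.ndarray) -> int:
        best = errors.min()
        cand = np.flatnonzero(errors <= best + 1e-12)
        # grid is ordered with both penalties descending: first tie is largest
        return int(cand[0])

    if shared_penalties:
        gi = _pick(cv_err.sum(axis=1))
        chosen = [gi] * p
    else:
        chosen = [_pick(cv_err[:, pi]) for pi in range(p)]

    coefs = np.zeros((q, p))
    intercepts = np.zeros(p)
    penalties: dict[str, NcrPenalty] = {}
    y_mean = Yarr.mean(axis=0)
    for pi, gi in enumerate(chosen):
        l1, l2 = grid[gi]
        beta_s = ncr_solve(Xs, Yarr[:, pi] - y_mean[pi], L, NcrPenalty(l1, l2))
        beta = beta_s / x_sd
        coefs[:, pi] = beta
        intercepts[pi] = y_mean[pi] - x_mean @ beta
        penalties[str(Y.feature_ids[pi])] = NcrPenalty(l1, l2)

    fitted = Xarr @ coefs + intercepts
    cv_table = pd.DataFrame(
        [
            {"response": Y.feature_ids[pi], "lambda1": g[0], "lambda2": g[1], "cv_mse": cv_err[gi, pi]}
            for pi in range(p)
            for gi, g in enumerate(grid)
        ]
    )
    return NcrFit(
        coefficients=pd.DataFrame(coefs, index=X.feature_ids, columns=Y.feature_ids),
        intercepts=pd.Series(intercepts, index=Y.feature_ids),
        penalties=penalties,
        fitted=pd.DataFrame(fitted, index=X.sample_ids, columns=Y.feature_ids),
        cv_table=cv_table,
        seed=seed,
    )


def grouping_check(beta: np.ndarray, net: IntensityMatrix) -> pd.DataFrame:
    """Per-edge gap |b_i/sqrt(s_i) - b_j/sqrt(s_j)| between connected predictors.

    The weighted mean gap (weights = edge intensities) summarizes how
    strongly the fit respects the grouping property; it is stored in
    ``result.attrs['weighted_mean_gap']`` (0.0 for an empty network).
    """
    beta = np.asarray(beta, dtype=float).ravel()
    w = net.to_numpy()
    if beta.shape[0] != w.shape[0]:
        raise ValueError("coefficient vector does not match the network's node count")
    s = w.sum(axis=1)
    scaled = np.where(s > 0, beta / np.sqrt(np.where(s > 0, s, 1.0)), 0.0)
    edges = net.edges()
    pos = {n: i for i, n in enumerate(net.node_ids)}
    gaps = [
        abs(scaled[pos[i]] - scaled[pos[j]]) for i, j in zip(edges["node_i"], edges["node_j"])
    ]
    report = edges.assign(gap=gaps)
    total_w = report["weight"].sum()
    report.attrs["weighted_mean_gap"] = (
        float((report["weight"] * report["gap"]).sum() / total_w) if total_w > 0 else 0.0
    )
    return report


def qtl_regions(fit: NcrFit, mmap: MarkerMap) -> dict[str, pd.DataFrame]:
    """Candidate QTL regions: mapped markers with non-zero NCR coefficients.

    Per response, returns rows (marker, chromosome, position, coefficient)
    for every predictor with a non-zero coefficient, sorted by chromosome
    then position. Marker regions highlighted this way are candidate QTLs;
    coefficient magnitude is retained as the evidence weight.
    """
    mapped = set(mmap.marker_ids)
    features = list(fit.coefficients.index)
    unmapped = [f for f in features if f not in mapped]
    if unmapped:
        raise ValueError(f"predictors missing from the marker map: {unmapped[:10]}")
    chrom_order = {c: i for i, c in enumerate(mmap.chromosomes)}
    map_tab = mmap.table.set_index("marker")
    out: dict[str, pd.DataFrame] = {}
    for resp in fit.response_ids:
        beta = fit.coefficients[resp]
        nz = beta[beta != 0]
        tab = pd.DataFrame(
            {
                "marker": nz.index,
                "chromosome": map_tab.loc[nz.index, "chromosome"].to_numpy(),
                "position": map_tab.loc[nz.index, "position"].to_numpy(),
                "coefficient": nz.to_numpy(),
            }
        )
        tab = tab.assign(_c=tab["chromosome"].map(chrom_order))
        tab = tab.sort_values(["_c", "position"], kind="stable").drop(columns="_c")
        out[str(resp)] = tab.reset_index(drop=True)
    return out
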