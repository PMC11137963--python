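"""Synthetic linked guiding/target datasets with known ground truth.

The generator emulates the study design the method targets: a recombinant
inbred line (RIL) population measured on several omics layers across a few
sample groups (developmental stages). Two guiding kinds are supported:

* ``ril-snp`` — binary {0,1} genotypes along chromosomes, each chromosome a
  first-order Markov chain with per-interval switch probability
  ``recombination_rate`` (adjacent-marker correlation 1 - 2r), evenly
  spaced map positions;
* ``ggm-expression`` — zero-mean Gaussian draws from a block-sparse,
  diagonally dominant precision matrix (within-block partial correlations
  non-zero, between-block zero).

Targets are sparse grouped linear functions of the guiding layer: targets
in the same module share one contiguous guiding block with equal
coefficients (the grouping structure the network-constrained penalty
assumes) plus Gaussian noise, with optional per-group mean shifts that the
preprocessing step is meant to remove.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, MarkerMap, OmicsMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_ril_genotypes",
    "simulate_ggm_guiding",
    "simulate_targets",
    "simulate_dataset",
    "evaluate_recovery",
    "sign_f1",
    "module_edge_set",
]


@dataclass
class SimulationConfig:
    """Study-scale defaults: 164 samples in 4 groups, 5 chromosomes, 200
    guiding variables, 24 targets in 4 modules of 5 active predictors each."""

    n_samples: int = 164
    n_groups: int = 4
    guiding_kind: str = "ril-snp"  # or "ggm-expression"
    n_guiding: int = 200
    n_chromosomes: int = 5
    recombination_rate: float = 0.1
    n_target: int = 24
    n_blocks: int = 4
    block_size: int = 5
    effect_size: float = 1.0
    noise_sd: float = 0.5
    group_shift_sd: float = 0.5
    coding: str = "0/1"  # or "-1/1"
    within_block_partial: float = 0.2  # ggm-expression only
    coefficient_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.guiding_kind not in ("ril-snp", "ggm-expression"):
            raise ValueError(f"unknown guiding_kind {self.guiding_kind!r}")
        if not 0 < self.recombination_rate <= 0.5:
            raise ValueError("recombination_rate must be in (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("n_samples", "n_guiding", "n_chromosomes", "n_target", "n_blocks", "block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls(**json.loads(text))


@dataclass
class GroundTruth:
    """What the generator knows: coefficients, modules and guiding structure."""

    true_coefficients: pd.DataFrame  # Q x P
    true_target_modules: dict[str, list]  # module label -> target ids
    true_guiding_precision: pd.DataFrame | None = None
    marker_map: MarkerMap | None = None

    def module_of(self) -> dict:
        return {t: m for m, ts in self.true_target_modules.items() for t in ts}


def _groups(n_samples: int, n_groups: int) -> pd.Series:
    labels = [f"G{i % n_groups + 1}" for i in range(n_samples)]
    return pd.Series(labels, index=[f"S{i+1}" for i in range(n_samples)])


def simulate_ril_genotypes(config: SimulationConfig) -> tuple[OmicsMatrix, MarkerMap]:
    """Binary RIL genotypes: per chromosome a {0,1} Markov chain with switch
    probability ``recombination_rate``; map positions evenly spaced over a
    100-unit chromosome."""
    rng = np.random.default_rng(config.seed)
    n, q, c = config.n_samples, config.n_guiding, config.n_chromosomes
    per_chrom = [q // c + (1 if i < q % c else 0) for i in range(c)]
    geno = np.empty((n, q), dtype=float)
    markers, chroms, positions = [], [], []
    col = 0
    for ci, m in enumerate(per_chrom):
        first = rng.integers(0, 2, size=n)
        geno[:, col] = first
        for k in range(1, m):
            switch = rng.random(n) < config.recombination_rate
            geno[:, col + k] = np.where(switch, 1 - geno[:, col + k - 1], geno[:, col + k - 1])
        step = 100.0 / (m - 1) if m > 1 else 0.0
        for k in range(m):
            markers.append(f"m{ci+1}_{k+1}")
            chroms.append(f"chr{ci+1}")
            positions.append(k * step)
        col += m
    if config.coding == "-1/1":
        geno = 2 * geno - 1
    values = pd.DataFrame(geno, index=[f"S{i+1}" for i in range(n)], columns=markers)
    mmap = MarkerMap(pd.DataFrame({"marker": markers, "chromosome": chroms, "position": positions}))
    return OmicsMatrix(values, group=_groups(n, config.n_groups)), mmap


def _block_precision(q: int, block_size: int, rho: float) -> np.ndarray:
    """Equicorrelated block precision: unit diagonal, ``-rho`` off-diagonal
    within blocks. PD requires ``rho * (block_size - 1) < 1``; ``rho`` is
    clipped to 90% of that bound if necessary."""
    theta = np.eye(q)
    if block_size > 1:
        bound = 1.0 / (block_size - 1)
        off = min(rho, 0.9 * bound)
    else:
        off = 0.0
    for start in range(0, q, block_size):
        stop = min(start + block_size, q)
        theta[start:stop, start:stop] = -off
        for i in range(start, stop):
            theta[i, i] = 1.0
    mineig = np.linalg.eigvalsh(theta).min()
    if mineig <= 1e-8:
        raise RuntimeError("constructed precision matrix is not positive definite")
    return theta


def simulate_ggm_guiding(config: SimulationConfig) -> tuple[OmicsMatrix, pd.DataFrame]:
    """Gaussian guiding data from a block-sparse precision matrix."""
    rng = np.random.default_rng(config.seed)
    q = config.n_guiding
    theta = _block_precision(q, config.block_size, config.within_block_partial)
    cov = np.linalg.inv(theta)
    draws = rng.multivariate_normal(np.zeros(q), cov, size=config.n_samples, method="cholesky")
    names = [f"g{j+1}" for j in range(q)]
    values = pd.DataFrame(draws, index=[f"S{i+1}" for i in range(config.n_samples)], columns=names)
    prec = pd.DataFrame(theta, index=names, columns=names)
    return (
        OmicsMatrix(values, group=_groups(config.n_samples, config.n_groups)),
        prec,
    )


def simulate_targets(
    guiding: OmicsMatrix, config: SimulationConfig, marker_map: MarkerMap | None = None,
    true_precision: pd.DataFrame | None = None,
) -> tuple[OmicsMatrix, GroundTruth]:
    """Targets as sparse grouped linear functions of the guiding layer.

    Module ``k`` of targets loads on the ``k``-th contiguous block of
    ``block_size`` guiding features with equal coefficients
    ``effect_size`` (optionally jittered), plus N(0, noise_sd^2) noise and
    optional per-group mean shifts (N(0, group_shift_sd^2) per group and
    target)."""
    rng = np.random.default_rng(config.seed + 1)
    q, p = guiding.n_features, config.n_target
    if config.n_blocks * config.block_size > q:
        raise ValueError(
            f"{config.n_blocks} blocks of {config.block_size} exceed Q={q} guiding features"
        )
    X = guiding.to_numpy()
    targets = [f"t{j+1}" for j in range(p)]
    beta = np.zeros((q, p))
    modules: dict[str, list] = {}
    # spread blocks evenly over the guiding features
    stride = q // config.n_blocks
    for pi, t in enumerate(targets):
        m = pi % config.n_blocks
        modules.setdefault(f"M{m+1}", []).append(t)
        start = m * stride
        coefs = np.full(config.block_size, config.effect_size)
        if config.coefficient_jitter > 0:
            coefs = coefs + rng.normal(0, config.coefficient_jitter, size=config.block_size)
        beta[start : start + config.block_size, pi] = coefs
    Y = X @ beta + rng.normal(0, config.noise_sd, size=(X.shape[0], p))
    if config.group_shift_sd > 0 and guiding.group is not None:
        for g in guiding.group.unique():
            shift = rng.normal(0, config.group_shift_sd, size=p)
            Y[(guiding.group == g).to_numpy()] += shift
    values = pd.DataFrame(Y, index=guiding.sample_ids, columns=targets)
    truth = GroundTruth(
        true_coefficients=pd.DataFrame(beta, index=guiding.feature_ids, columns=targets),
        true_target_modules=modules,
        true_guiding_precision=true_precision,
        marker_map=marker_map,
    )
    return OmicsMatrix(values, group=guiding.group), truth


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, GroundTruth]:
    """Full linked dataset (guiding X, target Y, ground truth)."""
    if config.guiding_kind == "ril-snp":
        X, mmap = simulate_ril_genotypes(config)
        Y, truth = simulate_targets(X, config, marker_map=mmap)
    else:
        X, prec = simulate_ggm_guiding(config)
        Y, truth = simulate_targets(X, config, true_precision=prec)
    return X, Y, truth


def module_edge_set(truth: GroundTruth) -> set[tuple]:
    """Undirected edges implied by target module co-membership."""
    edges = set()
    for members in truth.true_target_modules.values():
        members = sorted(members, key=str)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.add((members[i], members[j]))
    return edges


def evaluate_recovery(estimated: IntensityMatrix, truth: GroundTruth) -> dict:
    """Edge precision/recall/F1 of an estimated target network against the
    co-membership edge set of the true modules."""
    true_edges = module_edge_set(truth)
    nodes = set(estimated.node_ids)
    missing = {n for e in true_edges for n in e} - nodes
    if missing:
        raise ValueError(f"estimated network is missing true nodes: {sorted(missing)[:5]}")
    est_edges = {tuple(sorted(e, key=str)) for e in estimated.edge_set()}
    true_edges = {tuple(sorted(e, key=str)) for e in true_edges}
    tp = len(est_edges & true_edges)
    precision = tp / len(est_edges) if est_edges else 0.0
    recall = tp / len(true_edges) if true_edges else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "edge_precision": precision,
        "edge_recall": recall,
        "edge_f1": f1,
        "n_estimated_edges": len(est_edges),
        "n_true_edges": len(true_edges),
    }


def sign_f1(estimated: np.ndarray, truth: np.ndarray) -> float:
    """F1 of signed support recovery: a selected coefficient counts as a true
    positive only if its sign matches the true coefficient's."""
    est = np.asarray(estimated, dtype=float).ravel()
    tru = np.asarray(truth, dtype=float).ravel()
    if est.shape != tru.shape:
        raise ValueError("shape mismatch")
    sel = est != 0
    act = tru != 0
    tp = int((sel & act & (np.sign(est) == np.sign(tru))).sum())
    fp = int(sel.sum()) - tp
    fn = int(act.sum()) - tp
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0
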