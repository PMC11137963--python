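# Methods

## Model

`guidenet` treats a network as a Gaussian graphical model: variables are
jointly normal, and a zero off-diagonal entry θ_ij of the precision matrix
Θ = Σ⁻¹ means variables i and j are conditionally independent given all
others. The estimated intensity matrix is Ŵ = |Θ̂| off the diagonal. This
representation carries two assumptions worth keeping in mind: (near-)
normal margins after preprocessing, and a meaning of "association" that is
*conditional* — an edge is a direct dependency net of all other variables
in the same layer.

The guided pipeline assumes in addition that the target layer is (partly) a
linear function of the guiding layer: y_p = Xβ_p + ε_p. Step 2 estimates
β_p under an L1 penalty plus a network-smoothness penalty, and Step 3
rebuilds the target network on the fitted values Xβ̂_p only. The resulting
network therefore answers a narrower question than the unguided one: which
targets look alike *through the lens of the guiding layer*. Target
covariation orthogonal to X is deliberately discarded.

### Graphical lasso and penalty selection

The precision estimate maximizes log|Θ| − tr(SΘ) − λ‖Θ‖₁. Our solver is
scikit-learn's coordinate-descent graphical lasso, which penalizes
off-diagonal entries only; a diagonal penalty would shift the estimated
partial variances but not the edge pattern, and the off-diagonal convention
keeps two exact boundary properties used in the tests: λ ≥ max|S_ij|
implies an empty graph, and λ = 0 returns S⁻¹. S is the sample correlation
matrix by default (features standardized) so that a single λ is comparable
across features of different scales; a `standardize=False` switch keeps the
covariance.

λ is selected by StARS with the method's canonical defaults: T = 20
subsamples of size b = ⌊10√N⌋ (capped at N−1) drawn without replacement, a
descending log-spaced grid of 30 penalties from max|S_ij| down to 1% of it,
and instability threshold 0.05. The per-penalty instability is the mean
over node pairs of 2θ̂(1−θ̂), θ̂ being the edge's selection frequency across
subsamples; it is monotonized by a running maximum from the sparse end, and
the smallest penalty whose monotonized instability stays ≤ 0.05 is chosen.
Two implementation details:

* the grid is scanned from the sparse end and abandoned once the
  monotonized instability exceeds the threshold — no denser penalty can be
  selected after that point, so the (expensive, ill-conditioned) dense end
  of the path is never fit;
* if no grid point qualifies, the sparsest penalty is returned with a
  `threshold_exceeded` flag and a warning, never a silent failure.

Fitted values of strongly grouped targets can be nearly collinear, which
the coordinate-descent solver dislikes at small penalties. Inside
subsampling loops the solver therefore runs in a non-strict mode: a
max-iteration stall keeps the last iterate with a warning, and an outright
solver failure is retried with a small diagonal ridge (1e-3, then 5e-2,
relative to the mean diagonal) — a standard shrinkage repair for
ill-conditioned covariance inputs. Direct calls are strict and raise with
the final duality gap.

### The linear marker network

For mapped markers the guiding network is fixed, not estimated: consecutive
markers on a chromosome are linked with weight one minus their distance
relative to the chromosome span; non-consecutive and cross-chromosome pairs
get zero. Weights are invariant to shifting or rescaling positions, lie in
[0, 1), and a two-marker chromosome yields weight 0 (its only gap *is* the
span) — this degenerate case is allowed but warned about, and its markers
then act as isolated nodes in the penalty below. A chromosome whose
positions are all equal has no usable geometry and is an error.

### Network-constrained regression

The criterion for response p is

    ‖y_p − Xβ‖² + λ₁‖β‖₁ + λ₂ Σ_{i~j} W_ij (β_i/√s_i − β_j/√s_j)².

The quadratic term equals βᵀLβ for the strength-normalized Laplacian
L = I − S^{-1/2} W S^{-1/2} (rows/columns of zero-strength nodes set to 0),
an identity the tests assert to 1e-12. The criterion is solved by the
augmented-data reduction: stacking X with √λ₂·L^{1/2} and padding y with Q
zeros turns it into a plain LASSO, handed to scikit-learn's coordinate
descent. L^{1/2} comes from a symmetric eigendecomposition with negative
eigenvalues clipped at zero (L is PSD analytically; clipping guards
rounding). λ₁ = 0 short-circuits to the closed-form generalized ridge
solution.

Defaults and conventions:

* predictors are standardized to unit variance and responses centered
  inside `ncr_cv`; coefficients are reported on the original scale and
  `fitted = X @ coefficients + intercept` exactly;
* λ₁ grid: 10 log-spaced points from λ₁max = 2·max|Xᵀy| (the smallest
  penalty with an all-zero solution) down to 1% of it; λ₂ grid:
  {0, 0.1, 1, 10} × Q/trace(L), bracketing the plain-LASSO limit;
* penalties are chosen per response by 5-fold CV (shared, seeded fold
  assignment across responses) under the minimum-mean-squared-error rule,
  ties broken toward larger (λ₁, λ₂); a `shared_penalties` flag forces one
  pair for all responses;
* responses whose selected model is all-zero produce constant fitted
  columns; they are excluded from the Step-3 covariance (zero variance) and
  re-enter the final network as isolated nodes, listed in the manifest.

Within the CV loop the training-fold design is re-centered at the fold
means; predictions add the fold means back. Skipping this biases the fold
error by the square of the mean offset.

### Comparison and uncertainty

"Same number of edges" between guided and unguided networks is matched on a
penalty grid by closest achievable count (graphical-lasso paths rarely hit
an exact count); ties go to the larger penalty and the achieved count is
always reported. Edge uncertainty is the edge-wise standard deviation of
|Θ̂| over T subsampled refits at the fixed selected penalty; refits that
fail are skipped with a warning and more than half failing is an error.
Hub ranking is by degree, ties broken by strength then label, so output is
reproducible.

## Synthetic data

The generator emulates a RIL multi-omics study: N = 164 samples in 4
equal groups, 5 chromosomes, Q = 200 guiding variables, P = 24 targets in
4 modules — a desk-scale version of a population of a few hundred lines
with ~10³ markers and tens of annotated metabolites.

* **ril-snp**: per chromosome a first-order Markov chain over {0,1} with
  switch probability r (default 0.1), giving adjacent-marker correlation
  1 − 2r; positions evenly spaced over a 100-unit chromosome. Genotypes
  are coded {0,1} by default, {−1,1} via `coding="-1/1"`.
* **ggm-expression**: draws from a multivariate normal whose precision has
  equicorrelated blocks (unit diagonal, −ρ within blocks, ρ default 0.2;
  PD requires ρ < 1/(block_size − 1), enforced by clipping to 90% of the
  bound).
* **targets**: module k loads on the k-th contiguous guiding block with
  equal coefficients (default 1.0; a jitter option breaks exact equality),
  plus N(0, 0.5²) noise and per-group mean shifts (SD 0.5) that the
  group-centering preprocessing is meant to remove. Equal within-block
  coefficients make the benefit of the grouping penalty measurable.

What the generator does **not** emulate: linkage maps with realistic
(Haldane/Kosambi) distances, segregation distortion, non-normal metabolite
distributions, missing values, or targets influenced by unobserved layers.
Passing tests on these simulations therefore demonstrate correctness of the
machinery and the qualitative behavior of the method (grouped selection,
lower edge uncertainty after conditioning), not performance guarantees on
real data.

## Problem sizes used in the checks

The automated checks run three simulation studies chosen as the smallest
designs that still exercise the claims: (1) signed-support recovery of the
NCR under the grouped design N=150, Q=60, three active blocks of five with
equal coefficients and signal-to-noise 2, median over 20 replicates;
(2) module recovery of the full pipeline at the default study scale
(N=164, Q=200, P=24); (3) the guided-vs-unguided edge-SD comparison at
matched sparsity over 10 replicate datasets of N=120, Q=80, P=16. The
StARS settings in (2)–(3) use 10–15 subsamples and a 15–20 point grid with
floor at 5% of λmax; selections on these data sit well above the floor, so
the shorter path changes nothing but runtime.

## Numerical choices

* Edges are entries of |Θ̂| above 1e-8; intensity matrices symmetrize their
  input, clip values below 1e-10 to exact zero and force a zero diagonal.
* Sample covariance uses the unbiased (n−1) denominator; the variance
  filter likewise, with ties broken toward the earlier column.
* The coordinate-descent solvers (both LASSO and graphical lasso) are
  allowed to stall within an order of magnitude of their scaled tolerance
  before being declared non-convergent; their dual-gap estimates oscillate
  at that level on near-collinear inputs while the edge pattern and
  coefficients are long since stable.
* All subsampling, fold assignment and simulation draw from
  `numpy.random.default_rng(seed)`; the same seed reproduces every output
  bit-identically, and the run manifest records every seed and selected
  penalty.

## Known limitations

* Missing values are rejected at read time (an optional mean-imputation
  flag exists for convenience); no EM or matrix-completion support.
* Only L1-penalized NCR is implemented — no ridge or elastic-net variants
  of the network-constrained criterion, and no generalized linear
  responses.
* The guiding network is taken as given in Step 2; uncertainty in Ŵ(X) is
  not propagated into the coefficient estimates.
* StARS instability is computed over all node pairs, which for very large
  Q makes Step-1 estimation the dominant cost; the gene-expression route
  is practical to a few thousand variables, not tens of thousands (hence
  the top-variance prefilter).
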