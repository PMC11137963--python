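# guidenet

Guided network estimation for vertically integrated omics data.

In systems biology a downstream molecular layer (say, metabolites) is shaped
by upstream layers (SNPs, transcripts). `guidenet` reconstructs the network
of a **target** omics layer *conditioned on* the network of a **guiding**
layer upstream of it, so that two target variables end up connected only if
they depend on similar (or connected) guiding variables — metabolites with a
shared genetic or transcriptomic basis, rather than metabolites that merely
co-vary.

It is written for quantitative geneticists and systems biologists working
with sample-matched multi-omics panels (e.g. a recombinant inbred line
population measured for genotypes, expression and metabolite levels).

## The method

Let **Y** (N×P) be the target data and **X** (N×Q) the guiding data on the
same N samples. An undirected network over K variables is encoded as a
symmetric non-negative intensity matrix **W** (zero diagonal); the strength
of node *i* is s_i = Σ_j W_ij. Three steps:

1. **Guiding network.** Either estimate Ŵ(X) = |Θ̂| by the graphical lasso —
   maximize log|Θ| − tr(SΘ) − λ‖Θ‖₁ with the penalty λ chosen by StARS
   (the least regularization whose edge set is stable under random
   subsampling) — or construct it a priori. For mapped genetic markers the
   a-priori network is a linear chain: consecutive markers i, j=i+1 on a
   chromosome get weight 1 − (α_j − α_i)/(α_last − α_first), and markers on
   different chromosomes are never connected.

2. **Network-constrained regression (NCR).** Each target y_p is regressed
   on all Q guiding variables under

   β̂_p = argmin ‖y_p − Xβ‖² + λ₁‖β‖₁ + λ₂ Σ_{i~j} W_ij (β_i/√s_i − β_j/√s_j)²,

   a generalization of the elastic net in which the quadratic term smooths
   the strength-scaled coefficients of predictors that share an edge in
   Ŵ(X), so connected predictors enter the model together (the grouping
   property). The penalty pair (λ₁, λ₂) is chosen per response by 5-fold
   cross-validation; fitted values ŷ_p = Xβ̂_p are retained.

3. **Target network.** The graphical lasso + StARS is re-run on the fitted
   matrix Ŷ(X), giving Ŵ(Ŷ(X)) — the target network conditioned on the
   guiding structure. For comparison, the unguided network Ŵ(Y) is
   re-estimated at *matched sparsity* (the penalty whose edge count is
   closest to the guided network's), and every edge is classified as
   common or unique to either network. Edge uncertainty is quantified as
   the edge-wise standard deviation of |Θ̂| over subsampled refits at the
   selected penalty.

Because the L1 part of the NCR zeroes coefficients exactly, the set of
mapped markers with non-zero coefficients per response doubles as a
candidate-QTL report (`qtl_regions`).

## Worked example

Simulate a linked RIL-genotype/metabolite-like dataset (120 samples in 4
groups, 80 binary markers on 5 chromosomes, 16 targets in 4 modules whose
members load on the same marker block), remove group means, and run the
pipeline:

```python
import guidenet as gn

cfg = gn.SimulationConfig(
    n_samples=120, n_guiding=80, n_target=16, n_blocks=4, block_size=5, seed=1
)
X, Y, truth = gn.simulate_dataset(cfg)
Yc = gn.preprocess(Y, center_by_group=True)

model = gn.GuidedNetworkModel(Yc, X, marker_map=truth.marker_map)
result = model.fit(seed=1, stars_kwargs={"subsample_count": 15, "n_lambda": 20})
print(result.summary())
```

```
Guided network estimation
============================================================
samples: 120   targets: 16   guiding: 80
guiding network source: marker-map
target network: lambda = 0.03356, 34 of 120 possible edges (sparsity 0.2833)
unguided baseline: lambda = 0.04704, 33 edges (sparsity 0.275, matched)
mean edge SD: guided 0.05385 vs unguided 0.1026
edges: common 26, unique to guided 8, unique to unguided 7
top hubs (degree): t6 (7), t4 (6), t15 (5), t1 (5), t8 (5)
```

Reading the output: StARS picked λ = 0.0336 for the guided network (34 of
120 possible edges); the unguided baseline was re-estimated at the closest
achievable edge count (33). The guided network's edges are roughly twice as
stable under subsampling (mean edge SD 0.054 vs 0.103) — conditioning on
the marker structure strips out non-genetic covariation. Against the known
module structure the guided network scores

```python
>>> gn.evaluate_recovery(result.target_network, truth)
{'edge_precision': 0.706, 'edge_recall': 1.0, 'edge_f1': 0.828, ...}
```

`result.save("run/")` writes the networks, coefficients, fitted values,
edge-level comparison and a JSON manifest (seeds, selected penalties, edge
counts) sufficient to re-run the fit bit-identically.

The same pipeline is available from the shell:

```
guidenet simulate --out-dir sims/
guidenet run --guiding sims/X.tsv --target sims/Y.tsv --map sims/map.tsv \
             --group-column group --seed 7 --out-dir run/
guidenet compare --a run/target_network.tsv --b run/unguided_network.tsv --out diff.tsv
```

(`guide-net`, `ncr-fit` and `target-net` run the three steps individually.)

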