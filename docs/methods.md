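# Methods

This note documents the models, algorithms and numerical choices behind
`netrf`, and what the synthetic data generator does and does not emulate.

## Random walk with restart

The walk iterates `π_{t+1} = (1 − r) Aᵀ π_t + r π₀` on the row-normalized
adjacency `A` of an undirected, unweighted gene network. Parameters:

* `restart_probability r ∈ [0, 1]`, default **0.3** for the network+evidence
  priors (the value fixed throughout the study design this package
  follows); `r = 0` is pure topology, `r = 1` freezes `π₀`.
* `convergence_tolerance` (L1), default **1e-10**, `max_iterations`
  **1000**. Convergence is geometric at rate `1 − r`, so 1000 iterations
  are ample for `r ≥ 0.1`; if the cap is hit, the last iterate is
  returned with a `RuntimeWarning`.

Degenerate inputs:

* **Isolated genes** (zero degree) have no outgoing transitions. Their
  per-step mass is redirected to the restart distribution (a
  self-restart), which keeps every iterate a proper distribution; isolated
  genes still receive restart-derived weight.
* **`r = 0`** can oscillate on bipartite components under power
  iteration. Since the plain-walk equilibrium on a connected network is
  degree-proportional, the degree prior `deg_i / (2|E|)` is returned
  directly.
* **Disconnected networks with `r > 0`** need no special casing — the
  restart ties components together through `π₀`.
* The equilibrium is renormalized at the end; floating drift over the
  iterations is orders of magnitude below the 1e-9 mass tolerance.

Note that the deviation of the equilibrium from `π₀` is Θ(1 − r), so the
"`r → 1` recovers the marginal prior" limit is approached only linearly.

## Prior constructions

* Marginal evidence uses **Welch** (unequal-variance) two-sample t-tests;
  genes constant in both classes get p = 1. Welch is the safer default
  for expression data with group-dependent variances.
* FDR adjustment is **Benjamini–Hochberg** (statsmodels).
* The `−log p` weights are normalized to sum to one (L1): the walk needs
  a probability distribution as `π₀`. p-values are floored at 1e-300
  before the log to avoid infinite weights. If every p equals 1 the
  `−log p` prior is undefined; callers fall back to a uniform `π₀` with a
  logged warning (this happens routinely for `NetworkQ` under the Null
  scenario, where BH adjustment sends most p-values to 1).
* `Oracle` is a standard uniform-prior forest on the disease-gene columns
  only — a restriction of the feature set, with `mtry = ⌈√|D|⌉`.

## The forest

Binary-classification CART bagging, written for exact control over the
candidate draw:

* **Weighted candidate sampling.** At each node, `mtry` distinct genes
  are drawn with probabilities proportional to the prior via exponential
  keys (rank `log(Uᵢ)/wᵢ`, keep the `mtry` largest), which is equivalent
  to successive draws proportional to the remaining weights. Zero-weight
  genes are never drawn; if fewer than `mtry` genes have positive weight,
  all of them are used. With a uniform prior the keys are a monotone
  transform of the same uniforms the unweighted path ranks, so the
  weighted algorithm reduces to the standard forest *bit for bit* at the
  same seed — a property the tests assert node by node.
* **Splits** maximize Gini impurity decrease with thresholds at midpoints
  between consecutive distinct sorted values; a split must improve by
  more than 1e-12 (guards float noise on exactly-tied partitions). Ties
  are broken deterministically: smallest gene index, then smallest
  threshold. Candidates offering no improving split simply leave the node
  a leaf — candidates are not re-drawn.
* **Growth** is to purity by default (`min_node_size = 1`), on bootstrap
  samples of size n drawn with replacement; `mtry` defaults to `⌈√p⌉`.
* **Prediction** is majority vote over trees; exact vote and leaf ties go
  to class 0 (documented, deterministic).
* **Permutation importance** is computed on each tree's out-of-bag
  samples: base accuracy minus accuracy after permuting a gene's OOB
  values, averaged (unnormalized, accuracy-decrease units) over trees with
  non-empty OOB sets. Genes a tree never splits on contribute exactly
  zero to that tree, so only used genes are permuted — an exact shortcut.
* **Determinism.** All randomness flows from one seed through
  `SeedSequence` children (one per tree, and per tree in importance), so
  identical data + config + seed give bit-identical forests, predictions
  and importances.

## Gene selection

`top_k` cuts the importance ranking (ties broken by input gene order).
`recursive_elimination` drops `⌊0.10 · p_current⌋` (at least 1) of the
lowest-ranked genes per round, refitting the forest with
`mtry = ⌈√p_current⌉` each round, until a preset minimum remains; the last
round truncates to exactly `min_genes`. Across rounds the marginal
p-values are computed once on the full data and re-used (dropping columns
does not change per-gene tests), while network-derived priors are
recomputed on the subnetwork induced by the retained genes and
renormalized; if that subnetwork loses all its edges the round falls back
to a uniform prior with a logged warning. This is one defensible reading
of a procedure whose prior-updating details are genuinely open; it keeps
each round internally consistent without re-estimating marginal evidence.

## Synthetic data

The generator emulates module-structured bulk RNA-seq co-expression:

* **Network**: module sizes uniform in [10, 40] (first quartile lands in
  the 12–20 range used for disease-module sizes); each module wired by
  preferential attachment (2 edges per arriving gene); each new module's
  hub attached to already-placed genes drawn proportionally to current
  degree. This yields one fully connected graph, heavy-tailed degrees
  (log–log degree-frequency slope ≈ −1.5) and clear global hubs. It is a
  deliberately simple stand-in for heavier network simulators — the
  evaluation needs the qualitative structure (modules + power-law-like
  hubs), not a particular sampler.
* **Expression**: multivariate normal with precision matrix `Ω = I + E`,
  where `E` carries minus the per-edge partial correlations (magnitudes
  uniform in [0.1, 0.3], random sign) and is symmetrically scaled by
  `1/√(max(sᵢ,1)·max(s_j,1))` (sᵢ = row absolute sum) divided by 1.05 —
  this bounds the spectral radius below 1, guaranteeing positive
  definiteness while leaving low-degree genes' partial correlations
  essentially untouched. Latent values are mapped by Gaussian copula onto
  negative-binomial marginals with means log-uniform in [20, 2000] and
  dispersions uniform in [0.1, 0.6] (variance `μ + φμ²`) — ranges typical
  of bulk RNA-seq. Model-level randomness (edge coefficients, marginal
  parameters) is driven by the `ExpressionModel.seed`, so the generating
  model stays fixed while replications draw fresh samples.
* **Phenotype**: Bernoulli with `log-odds = Σ_{i∈D} βᵢ Xᵢ` on per-gene
  standardized expression and zero intercept, so the case fraction
  averages 1/2. Disease-module scenarios pick the module(s) whose size is
  closest to the target count (default: first quartile of module sizes,
  clipped to [12, 20]) among modules at least that large, and use *all*
  of the module's genes as `D`. In `*Topo` scenarios a main disease gene
  is drawn uniformly in the module and `βᵢ = π*ᵢ · β · |M|` from the
  restart walk (r = 0.3, the method's own value — the choice for
  effect-size assignment is open) on the module's induced subgraph, so
  effects decay with closeness to the main gene and sum exactly to
  `β·|M|`.

What the generator does **not** emulate: library-size variation and
normalization artifacts, batch effects, marginals calibrated to any real
cohort, zero inflation, or networks with weighted/directed edges. Passing
tests therefore demonstrate the methods' behavior under a clean
module-plus-copula world, not performance on real tumor cohorts.

## Evaluation harness

Per replication and method: build the prior on the training half, fit the
forest, rank by OOB permutation importance, keep the top `|D|` genes
(`k = 15` under the Null scenario, the midpoint of the 12–20 module-size
range, since no natural `|D|` exists), refit a **standard** uniform-prior
forest on the kept genes, and score it on the test half. The refit uses a
standard forest so that the prediction model is comparable across methods
and matches the Oracle benchmark's construction. The network is generated
once per scenario run and shared across replications; disease gene sets
and expression are redrawn per replication. A failed replication is
logged with its traceback and excluded from the averages, never silently
dropped.

Default problem sizes are deliberately desk-scale — p = 200 genes, n = 400
samples (200 train / 200 test), 200 trees, 10 replications — chosen so a
full scenario runs in a couple of minutes on one CPU while leaving the
qualitative contrasts (Oracle dominance, hub bias under the Null, effect
size monotonicity) clearly measurable. Full-scale settings (p = 1000 or
3000, n = 2000, 1000 trees, 100 replications) are reachable through the
same configuration objects.

## Known limitations

* The forest is binary-classification only; no regression or survival
  endpoints, categorical predictors, or missing-value handling.
* Importance is permutation-based only (no impurity importance, no
  conditional/actual-importance corrections); with non-uniform sampling
  priors the null distribution of importances is unknown, which is why
  selection relies on fixed `k` or a fixed elimination floor rather than
  an automated threshold.
* The weighted draw is exact but O(p) per node; very large p with deep
  trees will be slower than optimized C implementations.
* Networks are unweighted and undirected; interaction confidence scores
  are not used.
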