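# netrf — network-guided random forests for disease gene discovery

Complex diseases are rarely driven by a single gene: associated genes tend
to cluster into *disease modules* of a gene network (e.g. a protein–protein
interaction network). `netrf` implements and evaluates a **network-guided
random forest** for binary phenotypes from gene expression data, in which
the network is summarized into a *sampling probability of predictor
variables* that replaces the uniform candidate draw of the standard random
forest. The package is aimed at statistical bioinformaticians who want to
study — not just apply — this class of methods: it ships the forest itself,
the gene-selection procedures, a module-structured RNA-seq simulator, and
an evaluation harness for variable-selection and prediction performance.

## The method

Let `A` be the row-normalized adjacency matrix of the gene network. An
initial distribution `π₀` over genes (uniform, degree-based, or
proportional to `−log pᵢ` of per-gene Welch t-tests) is diffused by the
random walk with restart

```
π_{t+1} = (1 − r) Aᵀ π_t + r π₀,
```

whose equilibrium `π*` up-weights genes that are well connected, carry
marginal association evidence, or sit close to genes that do. The forest
is standard CART bagging with one change: at every node the `mtry = ⌈√p⌉`
candidate splitting variables are drawn *without replacement with
probabilities proportional to `π*`*. Genes are then ranked by out-of-bag
permutation importance and selected either as a top-`k` cut or by
recursive elimination (drop the 10% lowest-ranking genes, rebuild,
repeat until a preset minimum remains).

Six prior constructions are compared throughout: `Oracle` (forest
restricted to the true disease genes; benchmark), `StandardRF` (uniform),
`MarginalP` (`−log p`), `Topology` (degree-proportional, the `r = 0`
walk), and `NetworkP` / `NetworkQ` (walk with `r = 0.3` seeded with raw /
FDR-adjusted p-values).

The simulator builds a module-based network with power-law-like degrees,
draws expression from a Gaussian graphical model consistent with the
network (Gaussian copula onto negative-binomial count marginals), and
generates phenotypes from the logistic model
`log-odds = β₀ + Σ_{i∈D} βᵢ Xᵢ` with `β₀ = 0` on standardized expression,
under six scenarios (`Null`, `RanEqu`, `ModEqu`, `ModTopo`, `TwoModEqu`,
`TwoModTopo`); in the `*Topo` scenarios `βᵢ = π*ᵢ · β · |M|` decays with
topological closeness to a main disease gene, so effects always sum to
`β·|D|`.

## Worked example

`examples/01_network_priors.py` builds a 7-gene toy network with a hub and
compares priors when genes `A` (next to the hub) and `F` (peripheral)
carry the signal:

```
 gene degree   p-value  topology  marginal  walk r=0.3
  HUB      4  3.82e-01     0.333     0.030       0.205
    A      1  6.13e-05     0.083     0.299       0.125
    F      1  2.61e-08     0.083     0.538       0.237
```

The topology prior concentrates on `HUB` regardless of the data, the
marginal prior on `A` and `F`, and the walk prior blends both: the
isolated signal gene `F` is shrunk, the hub is lifted through its
neighbors. `examples/02_weighted_forest.py` through
`examples/04_simulation_study.py` walk through forest fitting, recursive
selection and a miniature scenario run; e.g. the latter prints, at toy
scale (60 genes, 3 replications, one disease module, β = 2):

```
    method            metric     mean       se
    Oracle misclassification 0.261111 0.005556
    Oracle       sensitivity 1.000000 0.000000
  NetworkP misclassification 0.300000 0.033333
  NetworkP       sensitivity 0.511111 0.058794
```

i.e. the Oracle predicts best and recovers all disease genes by
construction, while `NetworkP` recovers about half the module here.

A thin CLI mirrors the library: `netrf simulate | prioritize | select |
evaluate` (see `netrf --help`); all inputs and outputs are TSV.

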