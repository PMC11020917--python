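"""Synthetic data generator for the simulation study.

Three layers, mirroring how module-structured transcriptomes are usually
simulated:

1. **Network** — small modules are generated with preferential attachment
   and then joined through their hub genes, again preferentially, so that
   the overall degree distribution is heavy-tailed (power-law-like) and the
   graph has one giant component.
2. **Expression** — a Gaussian graphical model whose precision matrix has
   nonzeros exactly on the network edges (plus the diagonal); the latent
   Gaussian values are pushed through a Gaussian copula onto per-gene
   negative-binomial marginals to obtain RNA-seq-like counts.
3. **Phenotype** — a binary label from a logistic model on the standardized
   expression of a disease gene set ``D``:

       log-odds = beta0 + sum_{i in D} beta_i X_i,      beta0 = 0.

Six scenarios control ``D`` and the effect sizes ``beta_i``: ``Null`` (no
disease gene), ``RanEqu`` (random genes, equal effects), ``ModEqu`` /
``ModTopo`` (one disease module, equal / connectivity-decaying effects) and
``TwoModEqu`` / ``TwoModTopo`` (two disjoint modules).  In the *Topo*
scenarios a main disease gene is drawn in each module and effects decay
with topological closeness to it: ``beta_i = pi*_i * beta * |M|`` where
``pi*`` is the restart-walk equilibrium on the module seeded at the main
gene.  In every scenario with disease genes the effects sum to
``beta * |D|``, so ``beta`` is the average effect size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import DRWSettings, GeneNetwork, SamplingPrior, drw_equilibrium

logger = logging.getLogger(__name__)

SCENARIOS = ("Null", "RanEqu", "ModEqu", "ModTopo", "TwoModEqu", "TwoModTopo")

#: restart probability used when assigning connectivity-based effect sizes
EFFECT_RESTART_PROBABILITY = 0.3


def _rng_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class SimNetworkConfig:
    """Module-based scale-free network parameters.

    Module sizes are drawn uniformly in ``[min_module_size,
    max_module_size]`` until the gene budget is spent; each module is wired
    by preferential attachment and joined to the already-built part of the
    graph through hub genes, chosen proportionally to their current degree.
    Defaults give module-size first quartiles in the 12-20 gene range.
    """

    n_genes: int = 1000
    min_module_size: int = 10
    max_module_size: int = 40
    attachment_edges: int = 2
    inter_module_edges: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 3:
            raise ValueError("n_genes must be >= 3")
        if self.min_module_size < 3:
            raise ValueError("min_module_size must be >= 3")
        if self.max_module_size < self.min_module_size:
            raise ValueError("max_module_size must be >= min_module_size")
        if self.min_module_size > self.n_genes:
            raise ValueError("module sizes exceed the number of genes")


@dataclass(frozen=True)
class ExpressionModel:
    """Gaussian-graphical-model expression with negative-binomial marginals.

    ``partial_correlation_range`` bounds the magnitude of per-edge partial
    correlations (random sign).  Negative-binomial means are log-uniform in
    ``nb_mean_range`` and dispersions (phi, with variance mu + phi mu^2)
    uniform in ``nb_dispersion_range`` — ranges typical of bulk RNA-seq.
    The model-level randomness (edge coefficients, marginal parameters) is
    driven by ``seed`` so that the generating model can stay fixed while
    fresh samples are drawn per replication.
    """

    partial_correlation_range: tuple = (0.1, 0.3)
    nb_mean_range: tuple = (20.0, 2000.0)
    nb_dispersion_range: tuple = (0.1, 0.6)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.partial_correlation_range
        if not 0 <= lo <= hi < 1:
            raise ValueError("partial correlation magnitudes must lie in [0, 1)")
        if self.nb_mean_range[0] <= 0 or self.nb_dispersion_range[0] <= 0:
            raise ValueError("negative-binomial parameters must be positive")


@dataclass(frozen=True)
class DiseaseConfig:
    """Disease gene set and per-gene effect sizes of the logistic model."""

    scenario: str
    disease_genes: tuple
    effect_sizes: np.ndarray
    average_effect: float
    intercept: float = 0.0
    main_genes: tuple = ()

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        genes = tuple(str(g) for g in self.disease_genes)
        betas = np.asarray(self.effect_sizes, dtype=np.float64)
        if betas.shape != (len(genes),):
            raise ValueError("effect_sizes must align to disease_genes")
        if self.scenario == "Null" and genes:
            raise ValueError("Null scenario must have an empty disease set")
        if genes:
            target = self.average_effect * len(genes)
            if abs(betas.sum() - target) > 1e-9:
                raise ValueError(
                    f"effect sizes sum to {betas.sum()!r}, expected beta*|D| = {target!r}"
                )
        betas = betas.copy()
        betas.flags.writeable = False
        object.__setattr__(self, "disease_genes", genes)
        object.__setattr__(self, "effect_sizes", betas)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario,
                "gene_id": list(self.disease_genes),
                "beta": self.effect_sizes,
                "is_main_gene": [g in set(self.main_genes) for g in self.disease_genes],
            }
        )


@dataclass(frozen=True)
class ReplicationData:
    """One simulated dataset, split 50/50 into disjoint train and test halves."""

    network: GeneNetwork
    expression_train: pd.DataFrame
    expression_test: pd.DataFrame
    phenotype_train: np.ndarray
    phenotype_test: np.ndarray
    disease_config: DiseaseConfig
    seed: int


# ---------------------------------------------------------------------------
# network generation


def _module_sizes(config: SimNetworkConfig, rng: np.random.Generator) -> list:
    sizes: list[int] = []
    remaining = config.n_genes
    while remaining > 0:
        if remaining <= config.max_module_size and remaining < 2 * config.min_module_size:
            # tail too small to split further: one last module of what is left
            sizes.append(remaining)
            break
        s = int(rng.integers(config.min_module_size, config.max_module_size + 1))
        if remaining - s < config.min_module_size:
            s = remaining if remaining <= config.max_module_size else config.min_module_size
        sizes.append(s)
        remaining -= s
    if sizes and sizes[-1] < 3:
        sizes[-2] += sizes[-1]
        sizes.pop()
    return sizes


def generate_network(config: SimNetworkConfig) -> GeneNetwork:
    """Module-based network with power-law-like degrees.

    Modules are wired independently by preferential attachment; each new
    module is then tied into the existing graph by connecting its hub
    (highest-degree gene) to already-placed genes drawn proportionally to
    their current degree, so early hubs accumulate inter-module links and
    global hub genes emerge.
    """
    rng = np.random.default_rng(config.seed)
    sizes = _module_sizes(config, rng)
    width = len(str(config.n_genes))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)]

    edges: list[tuple[str, str]] = []
    modules: dict[str, int] = {}
    placed: list[str] = []          # genes already in the graph
    degree: dict[str, int] = {}
    start = 0
    for m, size in enumerate(sizes):
        members = gene_ids[start : start + size]
        start += size
        g = nx.barabasi_albert_graph(
            size, min(config.attachment_edges, size - 1), seed=int(rng.integers(2**31))
        )
        for u, v in g.edges:
            edges.append((members[u], members[v]))
            degree[members[u]] = degree.get(members[u], 0) + 1
            degree[members[v]] = degree.get(members[v], 0) + 1
        for gid in members:
            modules[gid] = m
            degree.setdefault(gid, 0)
        if placed:
            hub = max(members, key=lambda gid: (degree[gid], gid))
            weights = np.array([degree[gid] for gid in placed], dtype=np.float64)
            weights = weights / weights.sum()
            n_join = min(config.inter_module_edges, len(placed))
            targets = rng.choice(len(placed), size=n_join, replace=False, p=weights)
            for t in targets:
                edges.append((hub, placed[t]))
                degree[hub] += 1
                degree[placed[t]] += 1
        placed.extend(members)
    return GeneNetwork(gene_ids, edges, modules)


# ---------------------------------------------------------------------------
# expression generation


def _precision_matrix(network: GeneNetwork, model: ExpressionModel) -> np.ndarray:
    """Sparse precision matrix with nonzeros exactly on edges + diagonal.

    Edge entries are minus the drawn partial correlations; rows/columns are
    then symmetrically scaled so the matrix is strictly diagonally dominant
    in the normalized sense, which guarantees positive definiteness while
    leaving low-degree genes' partial correlations essentially untouched.
    """
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 0x0E56]))
    p = network.n_genes
    omega = np.eye(p)
    edges = network.edge_indices
    if edges.shape[0]:
        lo, hi = model.partial_correlation_range
        mag = rng.uniform(lo, hi, edges.shape[0])
        sign = rng.choice([-1.0, 1.0], edges.shape[0])
        rho = mag * sign
        E = np.zeros((p, p))
        E[edges[:, 0], edges[:, 1]] = -rho
        E[edges[:, 1], edges[:, 0]] = -rho
        s = np.abs(E).sum(axis=1)
        d = np.sqrt(np.maximum(s, 1.0))
        omega += (E / d[:, None] / d[None, :]) / 1.05
    return omega


def _nb_params(network: GeneNetwork, model: ExpressionModel) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([model.seed, 0x0E57]))
    p = network.n_genes
    lo, hi = model.nb_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), p))
    phi = rng.uniform(*model.nb_dispersion_range, p)
    return mu, phi


def generate_expression(
    network: GeneNetwork, model: ExpressionModel, n_samples: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate an (n_samples x n_genes) count matrix consistent with the network.

    Latent values are multivariate normal with the edge-sparse precision
    matrix; each gene's values are mapped through its normal CDF and the
    inverse CDF of its negative-binomial marginal (Gaussian copula), so
    rank dependence follows the network while marginals are overdispersed
    counts.
    """
    omega = _precision_matrix(network, model)
    try:
        sigma = np.linalg.inv(omega)
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:  # pragma: no cover - construction guarantees PD
        raise ValueError("precision matrix is not positive definite") from err
    sd = np.sqrt(np.diag(sigma))

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, network.n_genes)) @ chol.T
    u = stats.norm.cdf(z / sd)

    mu, phi = _nb_params(network, model)
    r = 1.0 / phi
    counts = stats.nbinom.ppf(u, r, r / (r + mu)).astype(np.int64)
    return pd.DataFrame(counts, columns=list(network.gene_ids))


def nb_marginal_moments(network: GeneNetwork, model: ExpressionModel) -> pd.DataFrame:
    """Target mean/variance of each gene's count marginal (for diagnostics)."""
    mu, phi = _nb_params(network, model)
    return pd.DataFrame(
        {"gene_id": list(network.gene_ids), "mean": mu, "variance": mu + phi * mu**2}
    )


# ---------------------------------------------------------------------------
# disease configuration and phenotype


def default_disease_gene_count(network: GeneNetwork) -> int:
    """First quartile of the module sizes, clipped to [12, 20]."""
    modules = network.module_assignments
    if not modules:
        raise ValueError("network has no module assignments")
    sizes = pd.Series(modules).value_counts().to_numpy()
    q1 = float(np.percentile(sizes, 25))
    return int(np.clip(round(q1), 12, 20))


def _pick_modules(network: GeneNetwork, n_modules: int, target: int, rng) -> list:
    modules = network.module_assignments
    if not modules:
        raise ValueError("module scenarios require a network with module assignments")
    sizes = pd.Series(modules).value_counts()
    eligible = sizes[sizes >= target]
    if len(eligible) < n_modules:
        raise ValueError(
            f"need {n_modules} module(s) with >= {target} genes, network has {len(eligible)}"
        )
    # closest in size to the target, random among ties
    order = sorted(
        eligible.index, key=lambda m: (abs(int(eligible[m]) - target), rng.random())
    )
    return list(order[:n_modules])


def _topo_effects(
    network: GeneNetwork, members: list, main_gene: str, beta: float
) -> np.ndarray:
    """Connectivity-decaying effects: beta_i = pi*_i * beta * |M|."""
    sub = network.induced_subgraph(members)
    pi0 = SamplingPrior.point_mass(sub.gene_ids, main_gene)
    pi_star = drw_equilibrium(
        sub, pi0, DRWSettings(restart_probability=EFFECT_RESTART_PROBABILITY)
    )
    return pi_star.probabilities * beta * len(members)


def assign_disease_config(
    network: GeneNetwork,
    scenario: str,
    beta: float = 1.0,
    n_disease_genes: int | None = None,
    seed: int = 0,
) -> DiseaseConfig:
    """Draw the disease gene set and effect sizes for one scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)

    if scenario == "Null":
        return DiseaseConfig(scenario, (), np.empty(0), beta)

    if n_disease_genes is None:
        n_disease_genes = (
            default_disease_gene_count(network)
            if network.module_assignments
            else 15
        )
    if n_disease_genes < 1:
        raise ValueError("n_disease_genes must be >= 1")

    if scenario == "RanEqu":
        if n_disease_genes > network.n_genes:
            raise ValueError("more disease genes requested than genes in the network")
        idx = rng.choice(network.n_genes, n_disease_genes, replace=False)
        genes = tuple(network.gene_ids[i] for i in sorted(idx))
        return DiseaseConfig(scenario, genes, np.full(len(genes), beta), beta)

    n_modules = 2 if scenario.startswith("TwoMod") else 1
    chosen = _pick_modules(network, n_modules, n_disease_genes, rng)
    genes: list[str] = []
    betas: list[np.ndarray] = []
    mains: list[str] = []
    for module in chosen:
        members = network.module_members(module)
        if scenario.endswith("Equ"):
            betas.append(np.full(len(members), beta))
        else:
            main = str(rng.choice(members))
            mains.append(main)
            betas.append(_topo_effects(network, members, main, beta))
        genes.extend(members)
    return DiseaseConfig(
        scenario, tuple(genes), np.concatenate(betas), beta, main_genes=tuple(mains)
    )


def generate_phenotype(
    expression: pd.DataFrame, config: DiseaseConfig, seed: int = 0
) -> np.ndarray:
    """Binary labels from the logistic model on standardized disease-gene expression."""
    rng = np.random.default_rng(seed)
    n = expression.shape[0]
    if not config.disease_genes:
        return (rng.random(n) < 0.5).astype(np.int8)
    missing = set(config.disease_genes) - set(map(str, expression.columns))
    if missing:
        raise ValueError(f"disease genes missing from expression: {sorted(missing)[:5]}")
    X = expression[list(config.disease_genes)].to_numpy(dtype=np.float64)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    log_odds = config.intercept + Xs @ config.effect_sizes
    prob = 1.0 / (1.0 + np.exp(-log_odds))
    return (rng.random(n) < prob).astype(np.int8)


# ---------------------------------------------------------------------------
# full replication


def generate_replication(
    scenario: str,
    beta: float = 1.0,
    n_samples: int = 2000,
    network: GeneNetwork | None = None,
    network_config: SimNetworkConfig | None = None,
    expression_model: ExpressionModel | None = None,
    n_disease_genes: int | None = None,
    seed: int = 0,
) -> ReplicationData:
    """One complete simulated dataset, equally split into train and test.

    Passing a pre-built ``network`` keeps it fixed across replications (as
    in the simulation design, where one network is shared by all scenarios);
    otherwise a network is generated from ``network_config``.
    """
    ss = np.random.SeedSequence(seed)
    s_net, s_dis, s_expr, s_phen, s_split = (_rng_int(c) for c in ss.spawn(5))
    if network is None:
        cfg = network_config or SimNetworkConfig()
        network = generate_network(
            SimNetworkConfig(
                n_genes=cfg.n_genes,
                min_module_size=cfg.min_module_size,
                max_module_size=cfg.max_module_size,
                attachment_edges=cfg.attachment_edges,
                inter_module_edges=cfg.inter_module_edges,
                seed=s_net,
            )
        )
    model = expression_model or ExpressionModel()
    config = assign_disease_config(
        network, scenario, beta=beta, n_disease_genes=n_disease_genes, seed=s_dis
    )
    expression = generate_expression(network, model, n_samples, seed=s_expr)
    phenotype = generate_phenotype(expression, config, seed=s_phen)

    n_train = n_samples // 2
    perm = np.random.default_rng(s_split).permutation(n_samples)
    train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return ReplicationData(
        network=network,
        expression_train=expression.iloc[train].reset_index(drop=True),
        expression_test=expression.iloc[test].reset_index(drop=True),
        phenotype_train=phenotype[train],
        phenotype_test=phenotype[test],
        disease_config=config,
        seed=seed,
    )
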