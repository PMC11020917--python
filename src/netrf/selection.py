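"""Gene ranking and selection.

Two routes: a direct top-k cut of the permutation importance ranking (the
estimand used in the simulation study), and a recursive elimination in
which the forest is rebuilt repeatedly while the 10% lowest-ranking genes
are discarded each round until a pre-set minimum number of genes remains
(the procedure used on experimental data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .forest import Forest, ForestConfig, fit_forest, permutation_importance
from .network import GeneNetwork, SamplingPrior
from .priors import MethodSpec, build_method_prior, marginal_pvalues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EliminationRound:
    """Genes entering one round and the importances the round assigned them."""

    retained_genes: tuple
    importance: np.ndarray


@dataclass(frozen=True)
class SelectionResult:
    final_genes: tuple
    rounds: tuple


def top_k(importance: np.ndarray, k: int, gene_ids=None):
    """The ``k`` genes (or indices) with largest importance.

    Ties are broken by input gene order (stable sort), which keeps the
    procedure deterministic.
    """
    imp = np.asarray(importance, dtype=np.float64)
    if not 1 <= k <= imp.shape[0]:
        raise ValueError(f"k must lie in [1, {imp.shape[0]}], got {k}")
    order = np.argsort(-imp, kind="stable")[:k]
    if gene_ids is None:
        return order.tolist()
    gene_ids = list(gene_ids)
    return [gene_ids[i] for i in order]


def _round_prior(
    spec: MethodSpec,
    genes: tuple,
    network: GeneNetwork | None,
    p_values: np.ndarray | None,
    disease_genes,
) -> SamplingPrior | None:
    """Prior for the currently retained genes; ``None`` means uniform.

    Marginal p-values are computed once on the full data and re-used (they
    do not change when genes are dropped); network-derived priors are
    recomputed on the subnetwork induced by the retained genes.
    """
    if spec.name == "StandardRF":
        return None
    if spec.name == "Oracle" and disease_genes is not None:
        disease_genes = [g for g in disease_genes if g in set(genes)]
        if not disease_genes:
            raise ValueError("no disease gene left among the retained genes")
    subnet = network.induced_subgraph(genes) if spec.uses_network else None
    if spec.uses_network and subnet.n_edges == 0:
        logger.warning(
            "induced subnetwork on %d retained genes has no edges; using a uniform prior",
            len(genes),
        )
        return None
    return build_method_prior(
        spec,
        genes,
        network=subnet,
        p_values=p_values,
        disease_genes=disease_genes,
    )


def recursive_elimination(
    expression,
    phenotype,
    method: MethodSpec | str,
    min_genes: int,
    network: GeneNetwork | None = None,
    drop_fraction: float = 0.10,
    ntree: int = 500,
    min_node_size: int = 1,
    seed: int = 0,
    gene_ids=None,
    disease_genes=None,
) -> SelectionResult:
    """Iteratively drop the lowest-ranking genes until ``min_genes`` remain.

    Each round rebuilds the method's prior on the retained genes, fits a
    forest with ``mtry = ceil(sqrt(p_current))``, ranks genes by OOB
    permutation importance and discards the ``floor(drop_fraction * p)``
    (at least 1) lowest-ranked genes.  When a drop would leave fewer than
    ``min_genes``, the current ranking is truncated to exactly
    ``min_genes`` instead and the procedure stops.
    """
    spec = MethodSpec.from_name(method) if isinstance(method, str) else method
    import pandas as pd

    if isinstance(expression, pd.DataFrame):
        gene_ids = tuple(map(str, expression.columns))
        X_full = expression.to_numpy(dtype=np.float64)
    else:
        X_full = np.asarray(expression, dtype=np.float64)
        if gene_ids is None:
            gene_ids = tuple(f"g{i}" for i in range(X_full.shape[1]))
        gene_ids = tuple(map(str, gene_ids))
    y = np.asarray(phenotype)

    p_total = len(gene_ids)
    if not 1 <= min_genes < p_total + 1:
        raise ValueError("min_genes must lie in [1, p]")
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in (0, 1)")
    if spec.uses_network and network is None:
        raise ValueError(f"method {spec.name} requires a network")

    # marginal tests once, on the full data (reused across rounds)
    p_values = marginal_pvalues(X_full, y) if spec.uses_marginal_tests else None
    col_of = {g: i for i, g in enumerate(gene_ids)}

    retained = list(gene_ids)
    rounds: list[EliminationRound] = []
    seed_seq = np.random.SeedSequence(seed)
    while True:
        cols = [col_of[g] for g in retained]
        sub_p = p_values[cols] if p_values is not None else None
        prior = _round_prior(spec, tuple(retained), network, sub_p, disease_genes)
        fit_seed, imp_seed = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in seed_seq.spawn(2))
        config = ForestConfig(
            ntree=ntree,
            mtry=math.ceil(math.sqrt(len(retained))),
            min_node_size=min_node_size,
            seed=fit_seed,
            prior=prior,
        )
        forest = fit_forest(X_full[:, cols], y, config, gene_ids=retained)
        imp = permutation_importance(forest, X_full[:, cols], y, seed=imp_seed)
        rounds.append(EliminationRound(tuple(retained), imp))

        cur = len(retained)
        drop = max(1, int(drop_fraction * cur))
        if cur - drop <= min_genes:
            final = top_k(imp, min_genes, retained)
            return SelectionResult(tuple(final), tuple(rounds))
        retained = top_k(imp, cur - drop, retained)


def elimination_schedule(p: int, min_genes: int, drop_fraction: float = 0.10) -> list:
    """Retained-set sizes per round (closed form of the drop arithmetic)."""
    sizes = [p]
    cur = p
    while True:
        drop = max(1, int(drop_fraction * cur))
        if cur - drop <= min_genes:
            sizes.append(min_genes)
            return sizes
        cur -= drop
        sizes.append(cur)
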