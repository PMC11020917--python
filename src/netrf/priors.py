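"""Construction of candidate-sampling priors for the compared methods.

Six methods are compared throughout the package:

``Oracle``
    standard forest restricted to the (known) disease genes; benchmark only.
``StandardRF``
    uniform sampling probability over all genes.
``MarginalP``
    probability proportional to ``-log p_i`` of per-gene two-sample t-tests.
``Topology``
    degree-proportional probability (the r = 0 walk equilibrium).
``NetworkP`` / ``NetworkQ``
    random walk with restart (r = 0.3) seeded with ``-log p_i`` of raw /
    FDR-adjusted t-test p-values respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import DRWSettings, GeneNetwork, SamplingPrior, degree_prior, drw_equilibrium

logger = logging.getLogger(__name__)

#: floor applied to p-values before taking logs, to avoid infinite weights
P_FLOOR = 1e-300


@dataclass(frozen=True)
class MethodSpec:
    """Declarative description of one prior-construction method."""

    name: str
    uses_network: bool
    uses_marginal_tests: bool
    restart_probability: float = 0.3

    @classmethod
    def from_name(cls, name: str) -> "MethodSpec":
        key = name.lower().replace("-", "").replace("_", "").replace(" ", "")
        try:
            return METHOD_SPECS[key]
        except KeyError:
            raise ValueError(
                f"unknown method {name!r}; choose from {sorted(m.name for m in METHOD_SPECS.values())}"
            ) from None


METHOD_SPECS = {
    "oracle": MethodSpec("Oracle", uses_network=False, uses_marginal_tests=False),
    "standardrf": MethodSpec("StandardRF", uses_network=False, uses_marginal_tests=False),
    "marginalp": MethodSpec("MarginalP", uses_network=False, uses_marginal_tests=True),
    "topology": MethodSpec("Topology", uses_network=True, uses_marginal_tests=False),
    "networkp": MethodSpec("NetworkP", uses_network=True, uses_marginal_tests=True),
    "networkq": MethodSpec("NetworkQ", uses_network=True, uses_marginal_tests=True),
}

METHOD_NAMES = tuple(m.name for m in METHOD_SPECS.values())


def marginal_pvalues(expression: np.ndarray, phenotype: np.ndarray) -> np.ndarray:
    """Welch two-sample t-test p-value per gene (column of ``expression``).

    Genes that are constant within both phenotype classes carry no marginal
    information and are assigned p = 1.
    """
    X = np.asarray(expression, dtype=np.float64)
    y = np.asarray(phenotype)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("expression must be (samples x genes) aligned to phenotype")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"phenotype must contain exactly two classes, got {classes!r}")
    g0, g1 = X[y == classes[0]], X[y == classes[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each phenotype class needs at least two samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(g0, g1, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=np.float64)
    p[~np.isfinite(p)] = 1.0  # zero variance in both groups -> no evidence
    return np.clip(p, np.finfo(np.float64).tiny, 1.0)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pi0_from_pvalues(p_values: np.ndarray, gene_ids) -> SamplingPrior:
    """Initial walk distribution with entry i proportional to ``-log p_i``.

    p-values are floored at ``P_FLOOR`` before the log; genes with p = 1 get
    weight zero.  Raises if every p equals 1 (no marginal information) — the
    caller is expected to fall back to a uniform distribution.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    weights = -np.log(np.clip(p, P_FLOOR, 1.0))
    if weights.sum() <= 0:
        raise ValueError("all p-values equal 1; -log(p) prior is undefined")
    return SamplingPrior.from_weights(gene_ids, weights)


def _pi0_or_uniform(p: np.ndarray, gene_ids) -> SamplingPrior:
    try:
        return pi0_from_pvalues(p, gene_ids)
    except ValueError:
        logger.warning("all marginal p-values equal 1; falling back to a uniform pi0")
        return SamplingPrior.uniform(gene_ids)


def build_method_prior(
    method: MethodSpec | str,
    gene_ids,
    network: GeneNetwork | None = None,
    expression: np.ndarray | None = None,
    phenotype: np.ndarray | None = None,
    disease_genes=None,
    p_values: np.ndarray | None = None,
) -> SamplingPrior:
    """Sampling prior over ``gene_ids`` for one of the six methods.

    ``p_values`` may be supplied to reuse precomputed raw marginal p-values
    (aligned to ``gene_ids``); otherwise they are computed from
    ``expression``/``phenotype`` when the method needs them.  For network
    methods the network must be aligned to ``gene_ids``.
    """
    spec = MethodSpec.from_name(method) if isinstance(method, str) else method
    gene_ids = tuple(str(g) for g in gene_ids)

    if spec.uses_network:
        if network is None:
            raise ValueError(f"method {spec.name} requires a gene network")
        if network.gene_ids != gene_ids:
            raise ValueError("network gene order must match gene_ids")

    if spec.name == "StandardRF":
        return SamplingPrior.uniform(gene_ids)

    if spec.name == "Oracle":
        if not disease_genes:
            raise ValueError("Oracle requires a known disease-gene set")
        disease = {str(g) for g in disease_genes}
        unknown = disease - set(gene_ids)
        if unknown:
            raise ValueError(f"disease genes not in gene list: {sorted(unknown)[:5]}")
        weights = np.array([1.0 if g in disease else 0.0 for g in gene_ids])
        return SamplingPrior.from_weights(gene_ids, weights)

    if spec.name == "Topology":
        return degree_prior(network)

    # remaining methods need marginal tests
    if p_values is None:
        if expression is None or phenotype is None:
            raise ValueError(f"method {spec.name} requires expression and phenotype (or p_values)")
        p_values = marginal_pvalues(expression, phenotype)
    p_values = np.asarray(p_values, dtype=np.float64)
    if p_values.shape[0] != len(gene_ids):
        raise ValueError("p_values must be aligned to gene_ids")

    if spec.name == "MarginalP":
        return _pi0_or_uniform(p_values, gene_ids)

    if spec.name == "NetworkQ":
        p_values = fdr_adjust(p_values)

    pi0 = _pi0_or_uniform(p_values, gene_ids)
    settings = DRWSettings(restart_probability=spec.restart_probability)
    return drw_equilibrium(network, pi0, settings)
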