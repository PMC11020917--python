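"""Simulation evaluation harness.

Runs the compared methods over independent simulated replications of a
scenario and aggregates three performance measures:

* **misclassification rate** — fraction of test-set labels the selected-gene
  forest gets wrong, averaged over replications;
* **sensitivity** — fraction of true disease genes among the selected genes
  (only defined when disease genes exist);
* **false-selection counts** — per gene, the number of replications in
  which a method selected it (the false-selection diagnostic in the Null
  scenario, where hub genes tend to be picked spuriously by topology-aware
  priors).

Per replication and method the pipeline is: build the method's sampling
prior on the training half, fit the weighted forest, rank genes by OOB
permutation importance, keep the top ``|D|`` genes (a configurable ``k``
when there are no disease genes), refit a standard uniform-prior forest on
the kept genes, and evaluate it on the test half.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import ForestConfig, fit_forest, permutation_importance, predict
from .network import GeneNetwork
from .priors import MethodSpec, build_method_prior, marginal_pvalues
from .selection import top_k
from .simdata import (
    ExpressionModel,
    ReplicationData,
    SimNetworkConfig,
    generate_network,
    generate_replication,
)

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("Oracle", "StandardRF", "MarginalP", "Topology", "NetworkP", "NetworkQ")


def misclassification_rate(predicted, truth) -> float:
    """Fraction of mismatching labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and true labels must be equal-length and non-empty")
    return float(np.mean(predicted != truth))


def sensitivity(selected_genes, disease_genes) -> float:
    """Proportion of disease genes among the selected genes: |sel ∩ D| / |D|."""
    disease = set(disease_genes)
    if not disease:
        raise ValueError("sensitivity is undefined for an empty disease-gene set")
    return len(set(selected_genes) & disease) / len(disease)


def false_selection_counts(selected_lists, gene_ids) -> pd.Series:
    """Per gene, in how many replications it appeared among the selected genes."""
    counts = pd.Series(0, index=list(gene_ids), dtype=np.int64, name="count")
    for genes in selected_lists:
        unknown = set(genes) - set(counts.index)
        if unknown:
            raise ValueError(f"selected genes outside the gene universe: {sorted(unknown)[:5]}")
        counts[list(set(genes))] += 1
    counts.index.name = "gene_id"
    return counts


@dataclass(frozen=True)
class ScenarioRun:
    """One simulation configuration: scenario x scale x methods."""

    scenario: str
    p: int = 200
    beta: float = 1.0
    n_samples: int = 400
    n_replications: int = 10
    methods: tuple = DEFAULT_METHODS
    ntree: int = 200
    n_select_null: int = 15
    n_disease_genes: int | None = None
    seed: int = 0


@dataclass
class EvaluationReport:
    """Aggregated results of a scenario run.

    ``metrics`` is tidy (scenario, method, beta, p, metric, mean, se);
    ``per_replication`` holds the raw per-replication values and
    ``selection_counts`` the per-method, per-gene selection frequencies.
    """

    metrics: pd.DataFrame
    per_replication: pd.DataFrame
    selection_counts: pd.DataFrame
    selected_genes: dict
    network: GeneNetwork | None = None


def _spawn_ints(ss: np.random.SeedSequence, n: int) -> list:
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(n)]


def _evaluate_method(
    spec: MethodSpec,
    rep: ReplicationData,
    ntree: int,
    n_select: int,
    seeds: list,
) -> tuple[float, float | None, list]:
    """(misclassification, sensitivity-or-None, selected genes) for one method."""
    network = rep.network
    gene_ids = network.gene_ids
    X_train = rep.expression_train
    disease = rep.disease_config.disease_genes
    fit_seed, imp_seed, refit_seed = seeds

    if spec.name == "Oracle":
        # restriction of the feature set to the known disease genes
        cols = list(disease)
        config = ForestConfig(
            ntree=ntree, mtry=math.ceil(math.sqrt(len(cols))), seed=fit_seed
        )
        forest = fit_forest(X_train[cols], rep.phenotype_train, config)
        selected = list(disease)
        labels, _ = predict(forest, rep.expression_test[cols])
        return (
            misclassification_rate(labels, rep.phenotype_test),
            sensitivity(selected, disease),
            selected,
        )

    prior = build_method_prior(
        spec,
        gene_ids,
        network=network if spec.uses_network else None,
        expression=X_train.to_numpy(dtype=np.float64),
        phenotype=rep.phenotype_train,
        disease_genes=disease or None,
    )
    config = ForestConfig(
        ntree=ntree,
        mtry=math.ceil(math.sqrt(len(gene_ids))),
        seed=fit_seed,
        prior=prior,
    )
    forest = fit_forest(X_train, rep.phenotype_train, config)
    imp = permutation_importance(forest, X_train, rep.phenotype_train, seed=imp_seed)
    selected = top_k(imp, n_select, gene_ids)

    refit = ForestConfig(
        ntree=ntree, mtry=math.ceil(math.sqrt(len(selected))), seed=refit_seed
    )
    final = fit_forest(X_train[selected], rep.phenotype_train, refit)
    labels, _ = predict(final, rep.expression_test[selected])
    mis = misclassification_rate(labels, rep.phenotype_test)
    sens = sensitivity(selected, disease) if disease else None
    return mis, sens, selected


def run_scenario(
    run: ScenarioRun,
    network: GeneNetwork | None = None,
    network_config: SimNetworkConfig | None = None,
    expression_model: ExpressionModel | None = None,
) -> EvaluationReport:
    """Execute one scenario over replications and aggregate the measures.

    The network is generated once and shared by all replications; a failed
    replication is logged with its error and excluded from the averages.
    """
    specs = [MethodSpec.from_name(m) for m in run.methods]
    if run.scenario == "Null":
        dropped = [s.name for s in specs if s.name == "Oracle"]
        if dropped:
            logger.warning("Oracle requires disease genes; skipped in the Null scenario")
        specs = [s for s in specs if s.name != "Oracle"]
    if not specs:
        raise ValueError("no applicable method for this run")

    master = np.random.SeedSequence(run.seed)
    net_ss, rep_master = master.spawn(2)
    if network is None:
        cfg = network_config or SimNetworkConfig(n_genes=run.p)
        if cfg.n_genes != run.p:
            raise ValueError("network_config.n_genes must match run.p")
        network = generate_network(
            SimNetworkConfig(
                n_genes=cfg.n_genes,
                min_module_size=cfg.min_module_size,
                max_module_size=cfg.max_module_size,
                attachment_edges=cfg.attachment_edges,
                inter_module_edges=cfg.inter_module_edges,
                seed=_spawn_ints(net_ss, 1)[0],
            )
        )
    elif network.n_genes != run.p:
        raise ValueError("network size must match run.p")

    rows = []
    selected_by_method: dict[str, list] = {s.name: [] for s in specs}
    rep_seeds = rep_master.spawn(run.n_replications)
    for r, rep_ss in enumerate(rep_seeds):
        data_seed, *method_seed_pool = _spawn_ints(rep_ss, 1 + 3 * len(specs))
        try:
            rep = generate_replication(
                run.scenario,
                beta=run.beta,
                n_samples=run.n_samples,
                network=network,
                expression_model=expression_model,
                n_disease_genes=run.n_disease_genes,
                seed=data_seed,
            )
            n_select = (
                len(rep.disease_config.disease_genes)
                if rep.disease_config.disease_genes
                else run.n_select_null
            )
            for m, spec in enumerate(specs):
                seeds = method_seed_pool[3 * m : 3 * m + 3]
                mis, sens, selected = _evaluate_method(spec, rep, run.ntree, n_select, seeds)
                selected_by_method[spec.name].append(selected)
                rows.append(
                    {
                        "replication": r,
                        "method": spec.name,
                        "misclassification": mis,
                        "sensitivity": sens,
                        "n_selected": len(selected),
                    }
                )
        except Exception:
            logger.exception("replication %d failed; excluded from the averages", r)
            continue

    if not rows:
        raise RuntimeError("every replication failed")
    per_rep = pd.DataFrame(rows)

    metric_rows = []
    for spec in specs:
        sub = per_rep[per_rep["method"] == spec.name]
        for metric in ("misclassification", "sensitivity"):
            vals = sub[metric].dropna().to_numpy(dtype=np.float64)
            if vals.size == 0:
                continue
            se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            metric_rows.append(
                {
                    "scenario": run.scenario,
                    "method": spec.name,
                    "beta": run.beta,
                    "p": run.p,
                    "metric": metric,
                    "mean": float(vals.mean()),
                    "se": se,
                    "n_replications": int(vals.size),
                }
            )
    metrics = pd.DataFrame(metric_rows)

    count_frames = []
    for name, lists in selected_by_method.items():
        counts = false_selection_counts(lists, network.gene_ids).reset_index()
        counts.insert(0, "method", name)
        count_frames.append(counts)
    selection_counts = pd.concat(count_frames, ignore_index=True)

    return EvaluationReport(
        metrics=metrics,
        per_replication=per_rep,
        selection_counts=selection_counts,
        selected_genes=selected_by_method,
        network=network,
    )
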