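"""Fit a network-guided forest and read off permutation importances.

Simulates a small module-structured dataset in which one module drives the
phenotype, then fits the standard forest (uniform candidate sampling) and
the network-guided forest (candidates drawn from the restart-walk prior)
and prints how many true disease genes each puts in its importance top-|D|.
"""

import math

import numpy as np

from netrf import (
    ForestConfig,
    build_method_prior,
    fit_forest,
    generate_replication,
    permutation_importance,
    predict,
    top_k,
    SimNetworkConfig,
)

rep = generate_replication(
    "ModEqu",
    beta=2.0,
    n_samples=300,
    network_config=SimNetworkConfig(n_genes=100, min_module_size=12, max_module_size=20),
    seed=42,
)
disease = set(rep.disease_config.disease_genes)
genes = rep.network.gene_ids
print(f"{len(genes)} genes, disease module of {len(disease)}: {sorted(disease)[:4]} ...")

for method in ("StandardRF", "NetworkP"):
    prior = build_method_prior(
        method,
        genes,
        network=rep.network,
        expression=rep.expression_train.to_numpy(float),
        phenotype=rep.phenotype_train,
    )
    config = ForestConfig(ntree=300, mtry=math.ceil(math.sqrt(len(genes))), seed=1, prior=prior)
    forest = fit_forest(rep.expression_train, rep.phenotype_train, config)
    imp = permutation_importance(forest, rep.expression_train, rep.phenotype_train, seed=2)
    selected = top_k(imp, len(disease), genes)
    labels, _ = predict(forest, rep.expression_test)
    err = np.mean(labels != rep.phenotype_test)
    hits = len(set(selected) & disease)
    print(
        f"{method:>10}: test misclassification {err:.3f}; "
        f"{hits}/{len(disease)} disease genes in the importance top-{len(disease)}"
    )

print(
    "\nBoth forests predict similarly, but the network-guided prior usually\n"
    "recovers more of the disease module among its top-ranked genes."
)
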