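"""Turn a gene network into candidate-sampling priors.

Builds a toy 7-gene network with a hub, then compares three priors: the
degree-proportional prior (pure topology, the r = 0 walk), the -log(p)
prior from marginal t-tests, and the restart-walk prior (r = 0.3) that
blends both.  Genes that are well connected *and* marginally associated
end up with the largest sampling probability.
"""

import numpy as np

from netrf import (
    DRWSettings,
    GeneNetwork,
    build_method_prior,
    degree_prior,
    drw_equilibrium,
    marginal_pvalues,
    pi0_from_pvalues,
)

genes = ["HUB", "A", "B", "C", "D", "E", "F"]
edges = [("HUB", g) for g in "ABCD"] + [("D", "E"), ("E", "F")]
network = GeneNetwork(genes, edges)

# synthetic two-group expression in which gene F (peripheral) and gene A
# (next to the hub) carry the signal
rng = np.random.default_rng(7)
y = np.repeat([0, 1], 30)
X = rng.normal(size=(60, 7))
X[:, genes.index("A")] += 1.2 * y
X[:, genes.index("F")] += 1.2 * y

p_values = marginal_pvalues(X, y)
topology = degree_prior(network)
marginal = pi0_from_pvalues(p_values, genes)
blended = drw_equilibrium(network, marginal, DRWSettings(restart_probability=0.3))

print(f"{'gene':>5} {'degree':>6} {'p-value':>9} {'topology':>9} {'marginal':>9} {'walk r=0.3':>11}")
for i, g in enumerate(genes):
    print(
        f"{g:>5} {network.degrees()[i]:>6d} {p_values[i]:>9.2e} "
        f"{topology.probabilities[i]:>9.3f} {marginal.probabilities[i]:>9.3f} "
        f"{blended.probabilities[i]:>11.3f}"
    )

print(
    "\nThe topology prior concentrates on HUB regardless of the data; the marginal\n"
    "prior on A and F; the walk prior keeps A high (signal + next to the hub),\n"
    "shrinks the isolated signal gene F, and lifts HUB through its neighbors."
)
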