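"""Gene networks and the random walk with restart (RWR).

The network-guided forest turns a gene network into a probability
distribution over genes by diffusing an initial distribution ``pi0`` with
the iteration

    pi_{t+1} = (1 - r) A^T pi_t + r pi0,

where ``A`` is the row-normalized adjacency matrix of the network and ``r``
is the restart probability.  The fixed point ``pi*`` ranks genes by
topological relevance to the genes carrying initial mass: high-degree genes,
genes with large initial weight, and genes close to either end up with high
equilibrium probability.  ``pi*`` is later used to draw candidate splitting
variables inside the forest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance on "probabilities sum to one"
MASS_TOL = 1e-9


@dataclass(frozen=True)
class SamplingPrior:
    """A probability distribution over an ordered list of genes.

    Used both as the initial distribution ``pi0`` of the random walk and as
    its equilibrium ``pi*`` that drives candidate-variable sampling in the
    forest.  Entries are non-negative and sum to one (within ``MASS_TOL``).
    """

    gene_ids: tuple
    probabilities: np.ndarray

    def __post_init__(self):
        gene_ids = tuple(str(g) for g in self.gene_ids)
        probs = np.asarray(self.probabilities, dtype=np.float64)
        if probs.ndim != 1 or len(gene_ids) != probs.shape[0]:
            raise ValueError("probabilities must be a 1-D vector aligned to gene_ids")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        if probs.shape[0] == 0:
            raise ValueError("empty prior")
        if np.any(probs < 0) or not np.all(np.isfinite(probs)):
            raise ValueError("probabilities must be finite and non-negative")
        if abs(probs.sum() - 1.0) > MASS_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {probs.sum()!r})")
        probs = probs.copy()
        probs.flags.writeable = False
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "probabilities", probs)

    @classmethod
    def uniform(cls, gene_ids: Sequence[str]) -> "SamplingPrior":
        p = len(gene_ids)
        return cls(tuple(gene_ids), np.full(p, 1.0 / p))

    @classmethod
    def point_mass(cls, gene_ids: Sequence[str], gene: str) -> "SamplingPrior":
        probs = np.zeros(len(gene_ids))
        probs[list(gene_ids).index(gene)] = 1.0
        return cls(tuple(gene_ids), probs)

    @classmethod
    def from_weights(cls, gene_ids: Sequence[str], weights: np.ndarray) -> "SamplingPrior":
        """Normalize a non-negative weight vector to a distribution."""
        w = np.asarray(weights, dtype=np.float64)
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must have positive total mass")
        return cls(tuple(gene_ids), w / total)

    def subset(self, gene_ids: Sequence[str]) -> "SamplingPrior":
        """Restrict to a gene subset and renormalize."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [index[g] for g in gene_ids]
        return SamplingPrior.from_weights(gene_ids, self.probabilities[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.gene_ids), "probability": self.probabilities}
        )


@dataclass(frozen=True)
class DRWSettings:
    """Parameters of the random walk with restart.

    restart_probability
        Probability ``r`` of jumping back to the source distribution at each
        step.  ``r = 0`` is the plain random walk (degree-proportional
        equilibrium), ``r = 1`` freezes ``pi0``.
    convergence_tolerance
        L1 threshold on successive iterates.
    max_iterations
        Iteration cap; the walk converges geometrically at rate ``1 - r``.
    """

    restart_probability: float = 0.3
    convergence_tolerance: float = 1e-10
    max_iterations: int = 1000

    def __post_init__(self):
        if not 0.0 <= self.restart_probability <= 1.0:
            raise ValueError("restart_probability must lie in [0, 1]")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class GeneNetwork:
    """Undirected, unweighted gene network over an ordered gene list.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    known gene.  ``module_assignments`` (gene -> module label) is optional
    and only used by the simulator.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        edges: Iterable[tuple],
        module_assignments: Mapping[str, int] | None = None,
    ):
        gene_ids = tuple(str(g) for g in gene_ids)
        if len(gene_ids) == 0:
            raise ValueError("network must contain at least one gene")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        index = {g: i for i, g in enumerate(gene_ids)}

        seen: set[tuple[int, int]] = set()
        dropped = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u not in index or v not in index:
                raise ValueError(f"edge endpoint not in gene list: {(u, v)}")
            if u == v:
                raise ValueError(f"self-loop on gene {u!r}")
            iu, iv = index[u], index[v]
            key = (iu, iv) if iu < iv else (iv, iu)
            if key in seen:
                dropped += 1
                continue
            seen.add(key)
        if dropped:
            logger.info("deduplicated %d duplicate/reversed edges", dropped)
        edge_arr = np.array(sorted(seen), dtype=np.int64).reshape(-1, 2)

        if module_assignments is not None:
            unknown = set(map(str, module_assignments)) - set(gene_ids)
            if unknown:
                raise ValueError(f"module assignment for unknown genes: {sorted(unknown)[:5]}")
            module_assignments = {str(g): m for g, m in module_assignments.items()}

        self._gene_ids = gene_ids
        self._index = index
        self._edge_idx = edge_arr
        self._modules = module_assignments

    # -- basic accessors ---------------------------------------------------

    @property
    def gene_ids(self) -> tuple:
        return self._gene_ids

    @property
    def n_genes(self) -> int:
        return len(self._gene_ids)

    @property
    def n_edges(self) -> int:
        return self._edge_idx.shape[0]

    @property
    def edges(self) -> list:
        return [(self._gene_ids[i], self._gene_ids[j]) for i, j in self._edge_idx]

    @property
    def edge_indices(self) -> np.ndarray:
        """Edges as an (m, 2) array of gene indices (i < j)."""
        return self._edge_idx.copy()

    @property
    def module_assignments(self) -> dict | None:
        return dict(self._modules) if self._modules is not None else None

    def index_of(self, gene: str) -> int:
        return self._index[str(gene)]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self._edge_idx[:, 0], 1)
            np.add.at(deg, self._edge_idx[:, 1], 1)
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix in gene order."""
        A = np.zeros((self.n_genes, self.n_genes))
        if self.n_edges:
            A[self._edge_idx[:, 0], self._edge_idx[:, 1]] = 1.0
            A[self._edge_idx[:, 1], self._edge_idx[:, 0]] = 1.0
        return A

    def module_members(self, module: int) -> list:
        if self._modules is None:
            raise ValueError("network has no module assignments")
        return [g for g in self._gene_ids if self._modules.get(g) == module]

    def induced_subgraph(self, gene_ids: Sequence[str]) -> "GeneNetwork":
        """Subnetwork on ``gene_ids`` (order preserved as given)."""
        keep = {str(g) for g in gene_ids}
        missing = keep - set(self._gene_ids)
        if missing:
            raise ValueError(f"unknown genes: {sorted(missing)[:5]}")
        edges = [(u, v) for u, v in self.edges if u in keep and v in keep]
        modules = (
            {g: m for g, m in self._modules.items() if g in keep}
            if self._modules is not None
            else None
        )
        return GeneNetwork(tuple(str(g) for g in gene_ids), edges, modules)

    # -- conversions and I/O ----------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._gene_ids)
        g.add_edges_from(self.edges)
        if self._modules is not None:
            nx.set_node_attributes(g, self._modules, "module")
        return g

    @classmethod
    def from_networkx(cls, graph: nx.Graph, gene_order: Sequence[str] | None = None) -> "GeneNetwork":
        order = tuple(map(str, gene_order)) if gene_order is not None else tuple(map(str, graph.nodes))
        modules = nx.get_node_attributes(graph, "module")
        modules = {str(g): m for g, m in modules.items()} or None
        return cls(order, [(str(u), str(v)) for u, v in graph.edges], modules)

    @classmethod
    def from_edge_list(
        cls,
        path,
        delimiter: str = "\t",
        header: bool = False,
        gene_order: Sequence[str] | None = None,
    ) -> "GeneNetwork":
        """Read a two-column edge list; gene IDs are taken verbatim as strings.

        Duplicate and reversed edges are deduplicated (count logged).  The
        gene order is either given explicitly or taken as order of first
        appearance in the file.
        """
        df = pd.read_csv(
            path, sep=delimiter, header=0 if header else None, usecols=[0, 1], dtype=str
        )
        pairs = df.to_numpy()
        if gene_order is None:
            seen: dict[str, None] = {}
            for u, v in pairs:
                seen.setdefault(u, None)
                seen.setdefault(v, None)
            gene_order = tuple(seen)
        return cls(gene_order, [tuple(p) for p in pairs])

    def to_edge_list(self, path, delimiter: str = "\t") -> None:
        pd.DataFrame(self.edges, columns=["gene_a", "gene_b"]).to_csv(
            path, sep=delimiter, index=False
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneNetwork(n_genes={self.n_genes}, n_edges={self.n_edges})"


def row_normalize_adjacency(network: GeneNetwork) -> np.ndarray:
    """Row-stochastic adjacency matrix; zero-degree rows stay all-zero.

    Rows of isolated (dangling) genes cannot be normalized; they are left at
    zero here and the walk reassigns their outgoing mass to the restart
    distribution (see :func:`drw_equilibrium`).
    """
    A = network.adjacency()
    deg = A.sum(axis=1)
    dangling = deg == 0
    if dangling.any():
        logger.info("%d isolated gene(s) produce all-zero adjacency rows", int(dangling.sum()))
    out = np.divide(A, deg[:, None], out=np.zeros_like(A), where=~dangling[:, None])
    return out


def degree_prior(network: GeneNetwork) -> SamplingPrior:
    """Degree-proportional prior: gene i gets degree(i) / (2 |E|).

    This is the equilibrium of the plain (r = 0) random walk on a connected
    non-bipartite network, and is used directly as the topology-only prior.
    """
    if network.n_edges == 0:
        raise ValueError("degree prior undefined on an edgeless network")
    deg = network.degrees().astype(np.float64)
    return SamplingPrior(network.gene_ids, deg / (2.0 * network.n_edges))


def drw_equilibrium(
    network: GeneNetwork, pi0: SamplingPrior, settings: DRWSettings | None = None
) -> SamplingPrior:
    """Iterate the restart walk to its equilibrium distribution ``pi*``.

    Isolated genes have no outgoing transitions; their mass is redirected to
    the restart distribution at every step (a self-restart), which keeps the
    iterates proper probability distributions.  With ``r = 0`` the iteration
    can oscillate on bipartite components, so the degree-proportional
    equilibrium is returned directly; with ``r = 1`` the walk never leaves
    the source and ``pi0`` is returned unchanged.
    """
    settings = settings or DRWSettings()
    if pi0.gene_ids != network.gene_ids:
        raise ValueError("pi0 is not aligned to the network's gene order")
    r = settings.restart_probability
    if r == 1.0:
        return pi0
    if r == 0.0:
        return degree_prior(network)

    W = row_normalize_adjacency(network)
    Wt = np.ascontiguousarray(W.T)
    dangling = network.degrees() == 0
    p0 = pi0.probabilities
    pi = p0.copy()
    converged = False
    for _ in range(settings.max_iterations):
        moved = Wt @ pi
        if dangling.any():
            moved = moved + pi[dangling].sum() * p0
        nxt = (1.0 - r) * moved + r * p0
        delta = np.abs(nxt - pi).sum()
        pi = nxt
        if delta < settings.convergence_tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"random walk did not converge within {settings.max_iterations} iterations "
            f"(last L1 change {delta:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    # float drift over many iterations is well below MASS_TOL; renormalize anyway
    return SamplingPrior(network.gene_ids, pi / pi.sum())
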