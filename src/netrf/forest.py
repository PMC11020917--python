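"""CART-based binary classification forest with weighted candidate sampling.

This is the package's own forest implementation.  It differs from a
standard random forest in exactly one place: at every node, the ``mtry``
candidate splitting variables are drawn *without replacement with
probabilities proportional to a sampling prior* instead of uniformly.  A
uniform prior recovers the standard algorithm bit-for-bit (see
``sample_candidates``).

Trees are grown to purity on bootstrap samples, split by Gini impurity
decrease with midpoint thresholds, and stored as flat arrays so that
prediction and out-of-bag (OOB) permutation importance are vectorized.

Determinism: all randomness flows from ``ForestConfig.seed`` through
``numpy.random.SeedSequence`` children (one per tree), so identical inputs
give bit-identical forests, predictions and importances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .network import SamplingPrior

logger = logging.getLogger(__name__)

#: splits must decrease Gini impurity by more than this to be accepted
_MIN_IMPROVEMENT = 1e-12


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyper-parameters.

    ``mtry`` defaults to ``ceil(sqrt(p))``; ``min_node_size`` is the node
    size at or below which growth stops (1 = grow to purity); ``prior`` is
    the candidate-sampling distribution (``None`` = uniform, the standard
    forest).
    """

    ntree: int = 500
    mtry: int | None = None
    min_node_size: int = 1
    seed: int = 0
    prior: SamplingPrior | None = None

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")


@dataclass
class Tree:
    """One fitted tree in flat-array form.

    ``feature[k] == -1`` marks node ``k`` as a leaf; internal nodes route a
    sample left iff ``x[feature[k]] <= threshold[k]``.  ``counts[k]`` holds
    the (class 0, class 1) training counts of the node and ``pred[k]`` the
    majority class (ties -> class 0).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    counts: np.ndarray
    pred: np.ndarray
    bootstrap_indices: np.ndarray
    oob_indices: np.ndarray
    used_features: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.shape[0]

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index reached by each row of ``X``."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = np.nonzero(self.feature[node] >= 0)[0]
        while active.size:
            nd = node[active]
            f = self.feature[nd]
            go_left = X[active, f] <= self.threshold[nd]
            node[active] = np.where(go_left, self.left[nd], self.right[nd])
            active = active[self.feature[node[active]] >= 0]
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pred[self.apply(X)]


@dataclass
class Forest:
    """A fitted ensemble plus the bookkeeping needed for OOB importance."""

    trees: list
    gene_ids: tuple
    config: ForestConfig
    n_train: int

    @property
    def ntree(self) -> int:
        return len(self.trees)

    def predict(self, expression) -> tuple[np.ndarray, np.ndarray]:
        return predict(self, expression)


def sample_candidates(prior: SamplingPrior, mtry: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``mtry`` distinct gene indices with probability proportional to the prior.

    Sampling without replacement uses exponential keys: gene ``i`` receives
    key ``log(U_i) / w_i`` and the ``mtry`` largest keys win, which is
    equivalent to successive draws proportional to the remaining weights.
    If fewer than ``mtry`` genes have positive weight, all positive-weight
    genes are returned.  Zero-weight genes are never selected.
    """
    w = prior.probabilities
    n_pos = int(np.count_nonzero(w))
    if n_pos == 0:
        raise ValueError("sampling prior has no positive-weight gene")
    return _draw_candidates(w, min(mtry, n_pos), rng)


def _draw_candidates(weights: np.ndarray, mtry: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted candidate draw (``mtry`` must not exceed the positive-weight count).

    Consumes exactly ``p`` uniforms and, with uniform weights, ranks by a
    strictly monotone transform of them — so it selects the same candidate
    set as the unweighted path at the same generator state.
    """
    p = weights.shape[0]
    u = rng.random(p)
    if mtry >= p:
        return np.nonzero(weights > 0)[0]
    with np.errstate(divide="ignore"):
        keys = np.log(u) / weights  # w = 0 -> -inf, never selected
    return np.sort(np.argpartition(keys, p - mtry)[p - mtry:])


def _draw_candidates_uniform(p: int, mtry: int, rng: np.random.Generator) -> np.ndarray:
    """Dedicated unweighted path: rank p uniforms, keep the mtry largest."""
    u = rng.random(p)
    if mtry >= p:
        return np.arange(p)
    return np.sort(np.argpartition(u, p - mtry)[p - mtry:])


def best_split(
    X: np.ndarray, y: np.ndarray, sample_idx: np.ndarray, candidates: np.ndarray
) -> tuple[int, float, float] | None:
    """Best Gini split of a node over candidate genes, or ``None``.

    Thresholds sit at midpoints between consecutive distinct sorted values.
    Ties are broken deterministically: smallest gene index, then smallest
    threshold (``candidates`` must be sorted ascending).  Returns
    ``(gene, threshold, impurity_decrease)``.
    """
    n = sample_idx.shape[0]
    yn = y[sample_idx]
    n1 = int(yn.sum())
    if n < 2 or n1 == 0 or n1 == n:
        return None

    Xs = X[np.ix_(sample_idx, candidates)]
    order = np.argsort(Xs, axis=0, kind="stable")
    xs = np.take_along_axis(Xs, order, axis=0)
    ys = yn[order].astype(np.float64)

    c1 = np.cumsum(ys, axis=0)[:-1]            # class-1 count left of each cut
    nl = np.arange(1, n, dtype=np.float64)[:, None]
    nr = n - nl
    c1r = n1 - c1
    parent = 1.0 - ((n1 / n) ** 2 + ((n - n1) / n) ** 2)
    # weighted child impurity, expanded: (nl/n) * (1 - (c1/nl)^2 - (c0/nl)^2)
    with np.errstate(invalid="ignore"):
        child = (
            (nl - (c1 ** 2 + (nl - c1) ** 2) / nl)
            + (nr - (c1r ** 2 + (nr - c1r) ** 2) / nr)
        ) / n
    decrease = parent - child
    decrease[xs[1:] <= xs[:-1]] = -np.inf      # no cut between tied values

    best_pos = np.argmax(decrease, axis=0)      # first max -> smallest threshold
    per_cand = decrease[best_pos, np.arange(candidates.shape[0])]
    j = int(np.argmax(per_cand))                # first max -> smallest gene index
    if not per_cand[j] > _MIN_IMPROVEMENT:
        return None
    i = best_pos[j]
    thr = 0.5 * (xs[i, j] + xs[i + 1, j])
    return int(candidates[j]), float(thr), float(per_cand[j])


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    bootstrap: np.ndarray,
    weights: np.ndarray | None,
    mtry: int,
    min_node_size: int,
    rng: np.random.Generator,
) -> tuple[list, list, list, list, list]:
    """Grow one tree; returns parallel node lists (feature, thr, left, right, counts)."""
    p = X.shape[1]
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    counts: list[tuple[int, int]] = []

    def new_node(idx: np.ndarray) -> int:
        k = len(feature)
        n1 = int(y[idx].sum())
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        counts.append((idx.shape[0] - n1, n1))
        return k

    root = new_node(bootstrap)
    stack: list[tuple[int, np.ndarray]] = [(root, bootstrap)]
    while stack:
        node, idx = stack.pop()
        c0, c1 = counts[node]
        n = c0 + c1
        if n <= min_node_size or c0 == 0 or c1 == 0:
            continue
        if weights is None:
            cand = _draw_candidates_uniform(p, mtry, rng)
        else:
            cand = _draw_candidates(weights, mtry, rng)
        split = best_split(X, y, idx, cand)
        if split is None:
            continue
        g, thr, _ = split
        mask = X[idx, g] <= thr
        li = new_node(idx[mask])
        ri = new_node(idx[~mask])
        feature[node] = g
        threshold[node] = thr
        left[node] = li
        right[node] = ri
        stack.append((ri, idx[~mask]))
        stack.append((li, idx[mask]))
    return feature, threshold, left, right, counts


def _as_matrix(expression, gene_ids: tuple | None) -> tuple[np.ndarray, tuple]:
    if isinstance(expression, pd.DataFrame):
        if gene_ids is not None:
            missing = set(gene_ids) - set(map(str, expression.columns))
            if missing:
                raise ValueError(f"expression is missing gene columns: {sorted(missing)[:5]}")
            expression = expression[list(gene_ids)]
        else:
            gene_ids = tuple(map(str, expression.columns))
        X = expression.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(expression, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("expression must be a 2-D samples x genes matrix")
        if gene_ids is None:
            gene_ids = tuple(f"g{i}" for i in range(X.shape[1]))
        elif len(gene_ids) != X.shape[1]:
            raise ValueError("gene_ids length does not match expression columns")
    return np.ascontiguousarray(X), tuple(map(str, gene_ids))


def fit_forest(expression, phenotype, config: ForestConfig, gene_ids=None) -> Forest:
    """Fit the forest on binary labels (0/1), growing trees on bootstrap samples.

    ``expression`` may be a DataFrame (columns = gene IDs) or an array.  If
    ``config.prior`` is set, its gene order defines the column order and the
    expression is aligned to it.
    """
    if config.prior is not None:
        gene_ids = config.prior.gene_ids
    X, gene_ids = _as_matrix(expression, tuple(gene_ids) if gene_ids is not None else None)
    y = np.asarray(phenotype)
    if y.shape[0] != X.shape[0]:
        raise ValueError("phenotype length does not match expression rows")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("phenotype must be coded 0/1")
    y = y.astype(np.int8)
    if y.min() == y.max():
        raise ValueError("phenotype must contain both classes")

    n, p = X.shape
    weights = None
    n_pos = p
    if config.prior is not None:
        weights = config.prior.probabilities
        n_pos = int(np.count_nonzero(weights))
        if n_pos == 0:
            raise ValueError("sampling prior has no positive-weight gene")
    mtry = config.mtry if config.mtry is not None else math.ceil(math.sqrt(p))
    if mtry > n_pos:
        logger.debug("mtry=%d exceeds %d positive-weight genes; using all of them", mtry, n_pos)
        mtry = n_pos

    trees: list[Tree] = []
    all_idx = np.arange(n)
    for child in np.random.SeedSequence(config.seed).spawn(config.ntree):
        rng = np.random.default_rng(child)
        bootstrap = rng.integers(0, n, n)
        oob = np.setdiff1d(all_idx, bootstrap, assume_unique=False)
        f, t, l, r, c = _grow_tree(X, y, bootstrap, weights, mtry, config.min_node_size, rng)
        counts = np.asarray(c, dtype=np.int64)
        pred = (counts[:, 1] > counts[:, 0]).astype(np.int8)  # tie -> class 0
        feat = np.asarray(f, dtype=np.int64)
        trees.append(
            Tree(
                feature=feat,
                threshold=np.asarray(t, dtype=np.float64),
                left=np.asarray(l, dtype=np.int64),
                right=np.asarray(r, dtype=np.int64),
                counts=counts,
                pred=pred,
                bootstrap_indices=bootstrap,
                oob_indices=oob,
                used_features=np.unique(feat[feat >= 0]),
            )
        )
    return Forest(trees=trees, gene_ids=gene_ids, config=config, n_train=n)


def predict(forest: Forest, expression) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over trees.

    Returns ``(labels, vote_fractions)`` where ``vote_fractions`` is an
    (n, 2) array of the per-class tree-vote shares.  Exact 50/50 ties go to
    class 0.
    """
    X, _ = _as_matrix(expression, forest.gene_ids)
    if X.shape[1] != len(forest.gene_ids):
        raise ValueError("expression does not match the forest's gene columns")
    votes1 = np.zeros(X.shape[0], dtype=np.int64)
    for tree in forest.trees:
        votes1 += tree.predict(X)
    frac1 = votes1 / forest.ntree
    labels = (frac1 > 0.5).astype(np.int8)
    return labels, np.column_stack([1.0 - frac1, frac1])


def permutation_importance(forest: Forest, expression, phenotype, seed: int = 0) -> np.ndarray:
    """OOB permutation importance per gene, in accuracy-decrease units.

    For each tree with a non-empty OOB set and each gene the tree actually
    splits on: OOB accuracy minus OOB accuracy after permuting that gene's
    values within the OOB set.  Contributions are averaged (unnormalized)
    over the trees with non-empty OOB sets; genes a tree never uses
    contribute exactly zero to it, so never-used genes score 0.
    """
    X, _ = _as_matrix(expression, forest.gene_ids)
    y = np.asarray(phenotype).astype(np.int8)
    if y.shape[0] != X.shape[0]:
        raise ValueError("phenotype length does not match expression rows")
    p = X.shape[1]
    imp = np.zeros(p)
    n_eff = 0
    for tree, child in zip(forest.trees, np.random.SeedSequence(seed).spawn(forest.ntree)):
        oob = tree.oob_indices
        if oob.size == 0:
            logger.warning("tree has an empty OOB set; skipped in importance")
            continue
        n_eff += 1
        rng = np.random.default_rng(child)
        Xo = X[oob].copy()
        yo = y[oob]
        base = float((tree.predict(Xo) == yo).mean())
        for g in tree.used_features:
            col = Xo[:, g].copy()
            Xo[:, g] = col[rng.permutation(oob.size)]
            acc = float((tree.predict(Xo) == yo).mean())
            Xo[:, g] = col
            imp[g] += base - acc
    if n_eff == 0:
        raise ValueError("no tree has a non-empty OOB set; importance undefined")
    return imp / n_eff


def importance_frame(forest: Forest, importance: np.ndarray) -> pd.DataFrame:
    """Tidy (gene_id, importance, rank) table, rank 1 = most important."""
    order = np.argsort(-importance, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, importance.shape[0] + 1)
    return pd.DataFrame(
        {"gene_id": list(forest.gene_ids), "importance": importance, "rank": rank}
    )
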