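"""Module-network learner: Bayesian-scored regression-tree regulation programs.

A module network couples a partition of genes into modules with one
"regulation program" per module: a binary regression tree over candidate
regulators' expression values whose leaves model the pooled expression of the
module's genes in the arrays routed to them.  Learning alternates between
fitting each module's tree (greedy top-down split search) and reassigning
genes to the module whose tree explains them best, always increasing a single
objective, the Bayesian score.

The score is the log marginal likelihood of the pooled leaf values under a
Normal-Gamma conjugate model: leaf values y_1..y_n are i.i.d. Normal(mu,
1/tau) with prior mu | tau ~ Normal(mu0, (lambda0*tau)^-1), tau ~
Gamma(alpha0, beta0).  Integrating mu and tau out gives the closed form

    log m(y) = lnG(a_n) - lnG(a0) + a0*ln(b0) - a_n*ln(b_n)
               + (ln(l0) - ln(l_n))/2 - (n/2)*ln(2*pi)

with l_n = l0 + n, a_n = a0 + n/2 and
b_n = b0 + ss/2 + l0*n*(ybar - mu0)^2 / (2*l_n), ss the centered sum of
squares.  With mu0 = 0 and a weak lambda0 this is a standard weakly
informative choice for mean-centered log2 data.

Everything is deterministic given (matrix, regulators, options, seed); the
seed controls only the k-means initialization and the gene order of
reassignment sweeps, which is exactly what makes independent runs differ.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .expression import ExpressionMatrix, LOG2_CENTERED, ScaleError

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ScoreHyperparameters:
    """Normal-Gamma prior and search-control parameters of the Bayesian score."""

    mu0: float = 0.0
    lambda0: float = 0.2
    alpha0: float = 2.0
    beta0: float = 1.0
    min_leaf_arrays: int = 2
    improve_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda0 <= 0 or self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("lambda0, alpha0, beta0 must be positive")
        if self.min_leaf_arrays < 1:
            raise ValueError("min_leaf_arrays must be >= 1")


def leaf_log_marginal_stats(n, S, Q, h: ScoreHyperparameters):
    """Vectorized leaf score from sufficient statistics (count, sum, sum sq)."""
    n = np.asarray(n, dtype=float)
    S = np.asarray(S, dtype=float)
    Q = np.asarray(Q, dtype=float)
    out = np.zeros(np.broadcast(n, S, Q).shape)
    pos = n > 0
    if not np.any(pos):
        return out if out.shape else float(out)
    npos, Spos, Qpos = n[pos], S[pos], Q[pos]
    ybar = Spos / npos
    ss = np.maximum(Qpos - Spos * ybar, 0.0)
    lam_n = h.lambda0 + npos
    a_n = h.alpha0 + npos / 2.0
    b_n = h.beta0 + 0.5 * ss + h.lambda0 * npos * (ybar - h.mu0) ** 2 / (2.0 * lam_n)
    out[pos] = (
        gammaln(a_n)
        - gammaln(h.alpha0)
        + h.alpha0 * math.log(h.beta0)
        - a_n * np.log(b_n)
        + 0.5 * (math.log(h.lambda0) - np.log(lam_n))
        - (npos / 2.0) * _LOG_2PI
    )
    return out if out.shape else float(out)


def leaf_log_marginal(values, h: ScoreHyperparameters = ScoreHyperparameters()) -> float:
    """Log marginal likelihood of one leaf's pooled values; 0 for n = 0."""
    y = np.asarray(values, dtype=float).ravel()
    if y.size == 0:
        return 0.0
    return float(leaf_log_marginal_stats(y.size, y.sum(), np.square(y).sum(), h))


# ---------------------------------------------------------------------------
# Regulation trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Internal node (regulator, split) or leaf (array context + pooled stats).

    An array is routed left iff the regulator's value in that array is > split.
    """

    regulator: str | None = None
    split: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    arrays: list[int] = field(default_factory=list)
    n: float = 0.0
    S: float = 0.0
    Q: float = 0.0
    score: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.regulator is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"arrays": self.arrays, "n": self.n, "S": self.S,
                    "Q": self.Q, "score": self.score}
        return {"regulator": self.regulator, "split": self.split,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "regulator" in d:
            return cls(regulator=d["regulator"], split=d["split"],
                       left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]))
        return cls(arrays=list(d["arrays"]), n=d["n"], S=d["S"], Q=d["Q"],
                   score=d["score"])


@dataclass
class RegulatoryTree:
    """A regulation program: binary tree whose leaves partition the arrays."""

    root: TreeNode
    score: float
    max_depth: int

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def regulators(self) -> set[str]:
        regs: set[str] = set()

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                regs.add(node.regulator)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return regs

    def depth(self) -> int:
        def walk(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(walk(node.left), walk(node.right))

        return walk(self.root)


def _make_leaf(arrays: np.ndarray, G: float, colsum: np.ndarray,
               colsumsq: np.ndarray, h: ScoreHyperparameters) -> TreeNode:
    n = G * arrays.size
    S = float(colsum[arrays].sum())
    Q = float(colsumsq[arrays].sum())
    return TreeNode(arrays=[int(a) for a in arrays], n=n, S=S, Q=Q,
                    score=float(leaf_log_marginal_stats(n, S, Q, h)))


def _best_split(arrays: np.ndarray, G: float, colsum: np.ndarray,
                colsumsq: np.ndarray, reg_values: np.ndarray,
                regulator_ids: list[str], leaf_score: float,
                h: ScoreHyperparameters, allowed: set[str] | None = None):
    """Best (regulator, split) over context-local midpoints, or None.

    Ties are broken by regulator input order, then by smaller split value
    (both via strict-improvement comparisons in scan order).  ``allowed``
    restricts the candidate regulators (used by the program-size cap).
    """
    best = None
    best_delta = h.improve_tol
    m = arrays.size
    for ri, rid in enumerate(regulator_ids):
        if allowed is not None and rid not in allowed:
            continue
        v = reg_values[ri, arrays]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        cut = np.nonzero(vs[:-1] < vs[1:])[0]  # split after position i (right = <= s)
        if cut.size == 0:
            continue
        sizes_right = cut + 1
        ok = (sizes_right >= h.min_leaf_arrays) & (m - sizes_right >= h.min_leaf_arrays)
        cut = cut[ok]
        if cut.size == 0:
            continue
        cs = np.concatenate([[0.0], np.cumsum(colsum[arrays][order])])
        cq = np.concatenate([[0.0], np.cumsum(colsumsq[arrays][order])])
        nr = G * (cut + 1).astype(float)
        Sr, Qr = cs[cut + 1], cq[cut + 1]
        nl = G * m - nr
        Sl, Ql = cs[-1] - Sr, cq[-1] - Qr
        deltas = (
            leaf_log_marginal_stats(nl, Sl, Ql, h)
            + leaf_log_marginal_stats(nr, Sr, Qr, h)
            - leaf_score
        )
        for j, d in zip(cut, deltas):
            if d > best_delta:
                best_delta = d
                split = 0.5 * (vs[j] + vs[j + 1])
                left_arrays = arrays[order[j + 1:]]
                right_arrays = arrays[order[: j + 1]]
                best = (rid, float(split), left_arrays, right_arrays)
    return best


def _grow(node: TreeNode, G: float, colsum: np.ndarray, colsumsq: np.ndarray,
          reg_values: np.ndarray, regulator_ids: list[str], depth_left: int,
          h: ScoreHyperparameters, used: frozenset,
          max_regulators: int | None) -> TreeNode:
    if depth_left <= 0 or len(node.arrays) < 2 * h.min_leaf_arrays:
        return node
    arrays = np.asarray(node.arrays, dtype=int)
    allowed = None
    if max_regulators is not None and len(used) >= max_regulators:
        allowed = set(used)
    found = _best_split(arrays, G, colsum, colsumsq, reg_values, regulator_ids,
                        node.score, h, allowed=allowed)
    if found is None:
        return node
    rid, split, left_arrays, right_arrays = found
    used = used | {rid}
    left = _make_leaf(left_arrays, G, colsum, colsumsq, h)
    right = _make_leaf(right_arrays, G, colsum, colsumsq, h)
    return TreeNode(
        regulator=rid,
        split=split,
        left=_grow(left, G, colsum, colsumsq, reg_values, regulator_ids,
                   depth_left - 1, h, used, max_regulators),
        right=_grow(right, G, colsum, colsumsq, reg_values, regulator_ids,
                    depth_left - 1, h, used, max_regulators),
    )


#: Regulation programs are small by definition: at most this many distinct
#: regulators may appear in one module's tree (splits beyond the cap reuse
#: regulators already in the program).  Without a cap, twenty depth-5 trees
#: would consume more regulator slots than a realistic candidate pool holds,
#: and the appearance-frequency ranking would saturate.
DEFAULT_MAX_REGULATORS_PER_PROGRAM = 2


def _learn_tree_stats(G: float, colsum: np.ndarray, colsumsq: np.ndarray,
                      reg_values: np.ndarray, regulator_ids: list[str],
                      max_depth: int, h: ScoreHyperparameters,
                      max_regulators: int | None =
                      DEFAULT_MAX_REGULATORS_PER_PROGRAM) -> RegulatoryTree:
    all_arrays = np.arange(colsum.size)
    root = _make_leaf(all_arrays, G, colsum, colsumsq, h)
    root = _grow(root, G, colsum, colsumsq, reg_values, regulator_ids,
                 max_depth, h, frozenset(), max_regulators)
    tree = RegulatoryTree(root=root, score=0.0, max_depth=max_depth)
    tree.score = sum(leaf.score for leaf in tree.leaves())
    return tree


def learn_tree(
    module_gene_values,
    regulator_values,
    regulator_ids: list[str] | None = None,
    max_depth: int = 5,
    h: ScoreHyperparameters = ScoreHyperparameters(),
    max_regulators: int | None = DEFAULT_MAX_REGULATORS_PER_PROGRAM,
) -> RegulatoryTree:
    """Greedy top-down regression tree over regulators for one module.

    ``module_gene_values`` is a gene x array matrix (DataFrame or ndarray) of
    the module members; ``regulator_values`` a regulator x array matrix over
    the same arrays.  At each leaf, every (regulator, context-local midpoint
    split) is scored by the gain in summed leaf log marginals; the best split
    is accepted iff the gain exceeds ``h.improve_tol`` and both children keep
    at least ``h.min_leaf_arrays`` arrays.
    """
    if isinstance(module_gene_values, pd.DataFrame):
        module_gene_values = module_gene_values.to_numpy()
    if isinstance(regulator_values, pd.DataFrame):
        if regulator_ids is None:
            regulator_ids = list(regulator_values.index)
        regulator_values = regulator_values.to_numpy()
    module_gene_values = np.atleast_2d(np.asarray(module_gene_values, dtype=float))
    regulator_values = np.atleast_2d(np.asarray(regulator_values, dtype=float))
    if module_gene_values.shape[0] == 0:
        raise ValueError("module must contain at least one gene")
    if module_gene_values.shape[1] != regulator_values.shape[1]:
        raise ValueError("module genes and regulators must share the array set")
    if regulator_ids is None:
        regulator_ids = [f"REG{i}" for i in range(regulator_values.shape[0])]
    return _learn_tree_stats(
        G=float(module_gene_values.shape[0]),
        colsum=module_gene_values.sum(axis=0),
        colsumsq=np.square(module_gene_values).sum(axis=0),
        reg_values=regulator_values,
        regulator_ids=list(regulator_ids),
        max_depth=max_depth,
        h=h,
        max_regulators=max_regulators,
    )


def _tree_score_for_stats(tree: RegulatoryTree, G: float, colsum: np.ndarray,
                          colsumsq: np.ndarray, h: ScoreHyperparameters) -> float:
    """Score an existing tree structure against (possibly different) module stats."""
    total = 0.0
    for leaf in tree.leaves():
        arrays = np.asarray(leaf.arrays, dtype=int)
        n = G * arrays.size
        total += float(leaf_log_marginal_stats(
            n, colsum[arrays].sum(), colsumsq[arrays].sum(), h))
    return total


def _refresh_leaf_stats(tree: RegulatoryTree, G: float, colsum: np.ndarray,
                        colsumsq: np.ndarray, h: ScoreHyperparameters) -> None:
    for leaf in tree.leaves():
        arrays = np.asarray(leaf.arrays, dtype=int)
        leaf.n = G * arrays.size
        leaf.S = float(colsum[arrays].sum())
        leaf.Q = float(colsumsq[arrays].sum())
        leaf.score = float(leaf_log_marginal_stats(leaf.n, leaf.S, leaf.Q, h))
    tree.score = sum(l.score for l in tree.leaves())


def gene_score_delta(
    gene_values,
    tree: RegulatoryTree,
    h: ScoreHyperparameters = ScoreHyperparameters(),
) -> float:
    """Marginal Bayesian-score contribution of one gene under a module's tree.

    Sum over leaves of score(pooled leaf values + the gene's values in the
    leaf's arrays) - score(pooled leaf values).  Exchangeable: only sufficient
    statistics enter.
    """
    y = np.asarray(gene_values, dtype=float)
    delta = 0.0
    for leaf in tree.leaves():
        arrays = np.asarray(leaf.arrays, dtype=int)
        yv = y[arrays]
        delta += float(
            leaf_log_marginal_stats(leaf.n + yv.size, leaf.S + yv.sum(),
                                    leaf.Q + np.square(yv).sum(), h)
        ) - float(leaf_log_marginal_stats(leaf.n, leaf.S, leaf.Q, h))
    return delta


# ---------------------------------------------------------------------------
# The full model
# ---------------------------------------------------------------------------


@dataclass
class ModuleNetworkModel:
    """A gene partition, one regulation tree per module, and the total score."""

    assignment: dict[str, int]
    trees: dict[int, RegulatoryTree]
    total_score: float
    seed: int
    sweep_log: list[float]
    max_depth: int
    hyperparameters: ScoreHyperparameters
    converged: bool = True

    @property
    def n_modules(self) -> int:
        return len(self.trees)

    def module_members(self, module: int) -> set[str]:
        return {g for g, m in self.assignment.items() if m == module}

    def to_json(self, path) -> None:
        payload = {
            "assignment": self.assignment,
            "trees": {str(m): {"root": t.root.to_dict(), "score": t.score,
                               "max_depth": t.max_depth}
                      for m, t in self.trees.items()},
            "total_score": self.total_score,
            "seed": self.seed,
            "sweep_log": self.sweep_log,
            "max_depth": self.max_depth,
            "hyperparameters": asdict(self.hyperparameters),
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ModuleNetworkModel":
        with open(path) as fh:
            d = json.load(fh)
        trees = {
            int(m): RegulatoryTree(root=TreeNode.from_dict(t["root"]),
                                   score=t["score"], max_depth=t["max_depth"])
            for m, t in d["trees"].items()
        }
        return cls(
            assignment=d["assignment"],
            trees=trees,
            total_score=d["total_score"],
            seed=d["seed"],
            sweep_log=d["sweep_log"],
            max_depth=d["max_depth"],
            hyperparameters=ScoreHyperparameters(**d["hyperparameters"]),
            converged=d["converged"],
        )


def _reassignment_sweep(values: np.ndarray, assignment: np.ndarray,
                        trees: dict[int, RegulatoryTree], M: int,
                        rng: np.random.Generator,
                        h: ScoreHyperparameters) -> np.ndarray:
    """One sequential gene-reassignment pass with online statistics updates.

    Genes are visited in seeded-random order; each is (virtually) removed from
    its module and inserted into the module maximizing its score delta, with
    moves that would empty the source module skipped and moves accepted only
    when they improve the total score by more than ``h.improve_tol``.
    """
    n_genes, n_arrays = values.shape
    # flat leaf bookkeeping across all modules
    leaf_module: list[int] = []
    leaf_arrays: list[np.ndarray] = []
    for m in range(M):
        for leaf in trees[m].leaves():
            leaf_module.append(m)
            leaf_arrays.append(np.asarray(leaf.arrays, dtype=int))
    F = len(leaf_arrays)
    leaf_module_arr = np.asarray(leaf_module)
    ind = np.zeros((n_arrays, F))
    for f, arrs in enumerate(leaf_arrays):
        ind[arrs, f] = 1.0
    gl_n = ind.sum(axis=0)                     # arrays per leaf
    GS = values @ ind                          # gene x leaf sums
    GQ = np.square(values) @ ind               # gene x leaf sums of squares

    pool_n = np.zeros(F)
    pool_S = np.zeros(F)
    pool_Q = np.zeros(F)
    for f in range(F):
        members = assignment == leaf_module_arr[f]
        pool_n[f] = members.sum() * gl_n[f]
        pool_S[f] = GS[members, f].sum()
        pool_Q[f] = GQ[members, f].sum()
    scores0 = leaf_log_marginal_stats(pool_n, pool_S, pool_Q, h)
    module_size = np.bincount(assignment, minlength=M)
    module_slices = [np.nonzero(leaf_module_arr == m)[0] for m in range(M)]

    for g in rng.permutation(n_genes):
        c = int(assignment[g])
        if module_size[c] <= 1:
            continue
        sl = module_slices[c]
        pool_n[sl] -= gl_n[sl]
        pool_S[sl] -= GS[g, sl]
        pool_Q[sl] -= GQ[g, sl]
        scores0[sl] = leaf_log_marginal_stats(pool_n[sl], pool_S[sl], pool_Q[sl], h)
        with_gene = leaf_log_marginal_stats(
            pool_n + gl_n, pool_S + GS[g], pool_Q + GQ[g], h)
        deltas = np.bincount(leaf_module_arr, weights=with_gene - scores0,
                             minlength=M)
        best = int(np.argmax(deltas))
        target = best if deltas[best] > deltas[c] + h.improve_tol else c
        sl = module_slices[target]
        pool_n[sl] += gl_n[sl]
        pool_S[sl] += GS[g, sl]
        pool_Q[sl] += GQ[g, sl]
        scores0[sl] = leaf_log_marginal_stats(pool_n[sl], pool_S[sl], pool_Q[sl], h)
        module_size[c] -= 1
        module_size[target] += 1
        assignment[g] = target
    return assignment


def learn_model(
    matrix: ExpressionMatrix,
    regulator_ids,
    M: int,
    seed: int = 0,
    max_depth: int = 5,
    max_sweeps: int = 20,
    h: ScoreHyperparameters = ScoreHyperparameters(),
    score_tol: float = 1e-4,
    max_regulators: int | None = DEFAULT_MAX_REGULATORS_PER_PROGRAM,
) -> ModuleNetworkModel:
    """Learn a module network: seeded k-means partition, then iterative
    tree-fitting and gene-reassignment sweeps until the total Bayesian score
    stops improving (< ``score_tol``) or ``max_sweeps`` is reached.

    Regulator probes are excluded from module membership, so a regulator can
    never be its own target.  Deterministic given (matrix, options, seed).
    """
    if matrix.scale != LOG2_CENTERED:
        raise ScaleError("learn_model expects a log2-centered matrix")
    regulator_ids = list(regulator_ids)
    missing = set(regulator_ids) - set(matrix.values.index)
    if missing:
        raise ValueError(f"regulators absent from matrix: {sorted(missing)[:5]} ...")
    if M < 2:
        raise ValueError("M must be >= 2")
    gene_ids = [g for g in matrix.values.index if g not in set(regulator_ids)]
    if len(gene_ids) < M:
        raise ValueError("fewer non-regulator genes than modules")
    values = matrix.values.loc[gene_ids].to_numpy()
    reg_values = matrix.values.loc[regulator_ids].to_numpy()

    # one k-means++ init per seed: seed-to-seed initialization diversity is
    # what makes independent runs of the iterative procedure differ
    km = KMeans(n_clusters=M, random_state=int(seed) % (2**32), n_init=1)
    assignment = km.fit_predict(values).astype(int)
    # k-means can leave a cluster empty on degenerate data; backfill from the largest
    for m in range(M):
        while (assignment == m).sum() == 0:
            donor = int(np.bincount(assignment, minlength=M).argmax())
            assignment[np.nonzero(assignment == donor)[0][0]] = m

    rng = np.random.default_rng(seed)
    h_use = h
    trees: dict[int, RegulatoryTree] = {}
    sweep_log: list[float] = []
    prev_score = -math.inf
    converged = False

    def module_stats(m: int):
        members = assignment == m
        sub = values[members]
        return float(sub.shape[0]), sub.sum(axis=0), np.square(sub).sum(axis=0)

    for sweep in range(max_sweeps):
        total = 0.0
        for m in range(M):
            G, colsum, colsumsq = module_stats(m)
            new_tree = _learn_tree_stats(G, colsum, colsumsq, reg_values,
                                         regulator_ids, max_depth, h_use,
                                         max_regulators)
            if m in trees:
                old_score = _tree_score_for_stats(trees[m], G, colsum,
                                                  colsumsq, h_use)
                if old_score > new_tree.score:
                    _refresh_leaf_stats(trees[m], G, colsum, colsumsq, h_use)
                    new_tree = trees[m]
            trees[m] = new_tree
            total += new_tree.score
        assignment = _reassignment_sweep(values, assignment, trees, M, rng, h_use)
        total = 0.0
        for m in range(M):
            G, colsum, colsumsq = module_stats(m)
            total += _tree_score_for_stats(trees[m], G, colsum, colsumsq, h_use)
        if sweep_log and total < sweep_log[-1] - 1e-9:
            raise AssertionError("sweep score decreased; monotonicity violated")
        sweep_log.append(total)
        if total - prev_score < score_tol:
            converged = True
            break
        prev_score = total
    if not converged:
        logger.warning("learn_model: stopped after %d sweeps without convergence",
                       max_sweeps)

    # final tree pass so the stored trees match the final assignment
    total = 0.0
    for m in range(M):
        G, colsum, colsumsq = module_stats(m)
        new_tree = _learn_tree_stats(G, colsum, colsumsq, reg_values,
                                     regulator_ids, max_depth, h_use,
                                     max_regulators)
        old_score = _tree_score_for_stats(trees[m], G, colsum, colsumsq, h_use)
        if old_score > new_tree.score:
            _refresh_leaf_stats(trees[m], G, colsum, colsumsq, h_use)
            new_tree = trees[m]
        trees[m] = new_tree
        total += new_tree.score
    if sweep_log and total < sweep_log[-1] - 1e-9:
        raise AssertionError("final tree pass decreased the score")
    sweep_log.append(total)

    return ModuleNetworkModel(
        assignment={g: int(m) for g, m in zip(gene_ids, assignment)},
        trees=trees,
        total_score=float(total),
        seed=int(seed),
        sweep_log=[float(s) for s in sweep_log],
        max_depth=max_depth,
        hyperparameters=h_use,
        converged=converged,
    )


def model_regulators(
    model: ModuleNetworkModel, matrix: ExpressionMatrix
) -> set[tuple[str, int, int]]:
    """(regulator, module, influence sign) for every regulator used by a tree.

    Sign is the sign of the Pearson correlation between the regulator's
    expression and the module's mean expression across arrays; an exactly-zero
    correlation yields sign 0 (excluded from signed groupings downstream).
    """
    out: set[tuple[str, int, int]] = set()
    for m, tree in model.trees.items():
        regs = tree.regulators()
        if not regs:
            continue
        members = sorted(model.module_members(m))
        mod_mean = matrix.values.loc[members].to_numpy().mean(axis=0)
        for r in regs:
            rvals = matrix.values.loc[r].to_numpy()
            if np.std(rvals) == 0 or np.std(mod_mean) == 0:
                sign = 0
            else:
                rho = float(np.corrcoef(rvals, mod_mean)[0, 1])
                sign = int(np.sign(rho))
            out.add((r, m, sign))
    return out
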