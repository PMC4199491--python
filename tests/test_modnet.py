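import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import imna
from imna import ScoreHyperparameters, gene_score_delta, leaf_log_marginal, learn_tree
from imna.modnet import leaf_log_marginal_stats

from conftest import SMALL_ATLAS, make_matrix


def numeric_log_marginal(y, h):
    """2-D numerical integration of the Normal-Gamma-Normal marginal.

    The integrand is rescaled by its value at an approximate posterior mode so
    the quadrature works on an O(1) function, and the (mu, tau) domain is a
    generous box around that mode.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    ybar, ss = y.mean(), np.sum((y - y.mean()) ** 2)
    mu_star = (h.lambda0 * h.mu0 + n * ybar) / (h.lambda0 + n)
    beta_n = h.beta0 + 0.5 * ss + \
        h.lambda0 * n * (ybar - h.mu0) ** 2 / (2 * (h.lambda0 + n))
    tau_star = (h.alpha0 + n / 2) / beta_n

    def log_f(mu, tau):
        return (np.sum(stats.norm.logpdf(y, mu, 1.0 / math.sqrt(tau)))
                + stats.norm.logpdf(mu, h.mu0, 1.0 / math.sqrt(h.lambda0 * tau))
                + stats.gamma.logpdf(tau, h.alpha0, scale=1.0 / h.beta0))

    scale = log_f(mu_star, tau_star)
    mu_sd = 1.0 / math.sqrt((h.lambda0 + n) * tau_star)

    # tensor-product Gauss-Legendre on (mu, log tau); the substitution
    # tau = e^u adds a Jacobian factor of tau
    mu_nodes, mu_w = np.polynomial.legendre.leggauss(400)
    u_nodes, u_w = np.polynomial.legendre.leggauss(500)
    mu_lo, mu_hi = mu_star - 60 * mu_sd, mu_star + 60 * mu_sd
    u_lo, u_hi = math.log(tau_star) - 28.0, math.log(tau_star) + 10.0
    mu = (mu_lo + mu_hi) / 2 + (mu_hi - mu_lo) / 2 * mu_nodes
    u = (u_lo + u_hi) / 2 + (u_hi - u_lo) / 2 * u_nodes
    tau = np.exp(u)
    M, T = np.meshgrid(mu, tau, indexing="ij")
    log_grid = (
        np.sum(stats.norm.logpdf(y[:, None, None], M[None], 1.0 / np.sqrt(T[None])),
               axis=0)
        + stats.norm.logpdf(M, h.mu0, 1.0 / np.sqrt(h.lambda0 * T))
        + stats.gamma.logpdf(T, h.alpha0, scale=1.0 / h.beta0)
        + np.log(T)  # Jacobian of tau = e^u
    )
    weights = np.outer(mu_w, u_w) * (mu_hi - mu_lo) / 2 * (u_hi - u_lo) / 2
    val = np.sum(weights * np.exp(log_grid - scale))
    return math.log(val) + scale


class TestLeafLogMarginal:
    def test_empty_leaf_scores_zero(self):
        assert leaf_log_marginal([]) == 0.0

    def test_unit_hyperparameter_closed_form(self):
        """A single zero observation under unit hyperparameters is the
        Student-t(nu=2, scale=sqrt(2)) density at 0, i.e. 1/4."""
        h = ScoreHyperparameters(mu0=0.0, lambda0=1.0, alpha0=1.0, beta0=1.0)
        assert leaf_log_marginal([0.0], h) == pytest.approx(math.log(0.25),
                                                            abs=1e-12)

    def test_symmetric_about_prior_mean(self):
        rng = np.random.default_rng(0)
        h = ScoreHyperparameters()
        for _ in range(10):
            y = rng.normal(size=rng.integers(1, 9))
            assert leaf_log_marginal(y, h) == pytest.approx(
                leaf_log_marginal(-y, h), abs=1e-10)

    def test_matches_numerical_integration(self):
        """Closed form vs 2-D quadrature on 50 random instances, n <= 8."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            y = rng.normal(0, 1.5, size=n)
            h = ScoreHyperparameters(
                mu0=float(rng.normal(0, 0.5)),
                lambda0=float(rng.uniform(0.1, 2.0)),
                alpha0=float(rng.uniform(0.5, 3.0)),
                beta0=float(rng.uniform(0.5, 2.0)),
            )
            assert leaf_log_marginal(y, h) == pytest.approx(
                numeric_log_marginal(y, h), abs=1e-4)

    def test_stats_form_matches_value_form(self):
        rng = np.random.default_rng(2)
        h = ScoreHyperparameters()
        y = rng.normal(size=20)
        assert float(leaf_log_marginal_stats(
            y.size, y.sum(), np.square(y).sum(), h)) == pytest.approx(
            leaf_log_marginal(y, h))


def naive_split_gain(module_values, reg_vector, split, h):
    """Score gain of one (regulator, split) pair, computed naively."""
    left = reg_vector > split
    root = leaf_log_marginal(module_values.ravel(), h)
    return (leaf_log_marginal(module_values[:, left].ravel(), h)
            + leaf_log_marginal(module_values[:, ~left].ravel(), h) - root)


def assert_split_is_enumeration_optimal(tree, module, regs, ids, h):
    """The learned depth-1 split must achieve the exhaustive-enumeration
    optimum; exactly tied optima (identical gains) are equivalent."""
    rid, split, best_delta = brute_force_depth1(module, regs, ids, h)
    if rid is None:
        assert tree.root.is_leaf
        return
    assert not tree.root.is_leaf
    learned = naive_split_gain(module, regs[ids.index(tree.root.regulator)],
                               tree.root.split, h)
    assert learned == pytest.approx(best_delta, rel=1e-9, abs=1e-9)


def brute_force_depth1(module_values, reg_values, regulator_ids, h):
    """Exhaustive search over every (regulator, midpoint split) pair."""
    best = (None, None, h.improve_tol)
    root_score = leaf_log_marginal(module_values.ravel(), h)
    for ri, rid in enumerate(regulator_ids):
        v = reg_values[ri]
        for s in sorted(set((a + b) / 2 for a, b in
                            itertools.pairwise(sorted(set(v))))):
            left = v > s
            if left.sum() < h.min_leaf_arrays or \
               (~left).sum() < h.min_leaf_arrays:
                continue
            delta = (leaf_log_marginal(module_values[:, left].ravel(), h)
                     + leaf_log_marginal(module_values[:, ~left].ravel(), h)
                     - root_score)
            if delta > best[2]:
                best = (rid, s, delta)
    return best


class TestLearnTree:
    def test_depth_zero_is_single_leaf(self):
        rng = np.random.default_rng(3)
        tree = learn_tree(rng.normal(size=(4, 8)), rng.normal(size=(3, 8)),
                          max_depth=0)
        assert tree.root.is_leaf
        assert sorted(tree.root.arrays) == list(range(8))

    def test_constant_module_never_splits(self):
        rng = np.random.default_rng(4)
        tree = learn_tree(np.full((5, 10), 1.3), rng.normal(size=(4, 10)),
                          max_depth=5)
        assert tree.root.is_leaf

    def test_planted_depth1_recovery(self):
        """Module mean +2 when the causal regulator is positive, -2 otherwise;
        the learned root must test that regulator with a split between the two
        value clusters, matching brute force."""
        rng = np.random.default_rng(5)
        reg = np.concatenate([rng.uniform(0.5, 1.5, 6), rng.uniform(-1.5, -0.5, 6)])
        decoys = rng.normal(size=(3, 12))
        regs = np.vstack([decoys[:2], reg, decoys[2:]])
        ids = ["D1", "D2", "CAUSAL", "D3"]
        module = np.where(reg > 0, 2.0, -2.0)[None, :].repeat(6, axis=0)
        tree = learn_tree(module, regs, regulator_ids=ids, max_depth=1)
        assert tree.root.regulator == "CAUSAL"
        assert reg.min() < tree.root.split < reg.max()
        assert max(reg[reg < 0]) < tree.root.split < min(reg[reg > 0])
        rid, split, _ = brute_force_depth1(module, regs, ids,
                                           ScoreHyperparameters())
        assert (tree.root.regulator, tree.root.split) == (rid, pytest.approx(split))

    def test_depth1_equals_exhaustive_enumeration(self):
        """20 random instances (<= 5 regulators, <= 8 arrays): the greedy
        depth-1 tree equals brute force over all (regulator, split) pairs."""
        rng = np.random.default_rng(6)
        h = ScoreHyperparameters()
        for _ in range(20):
            n_arr = int(rng.integers(4, 9))
            n_reg = int(rng.integers(1, 6))
            module = rng.normal(size=(int(rng.integers(1, 5)), n_arr))
            regs = rng.normal(size=(n_reg, n_arr))
            ids = [f"R{i}" for i in range(n_reg)]
            tree = learn_tree(module, regs, regulator_ids=ids, max_depth=1, h=h)
            assert_split_is_enumeration_optimal(tree, module, regs, ids, h)

    def test_depth_and_leaf_size_limits_hold(self):
        rng = np.random.default_rng(7)
        tree = learn_tree(rng.normal(size=(6, 30)), rng.normal(size=(5, 30)),
                          max_depth=3)
        assert tree.depth() <= 3
        for leaf in tree.leaves():
            assert len(leaf.arrays) >= 2

    def test_program_size_cap(self):
        rng = np.random.default_rng(8)
        tree = learn_tree(rng.normal(size=(6, 40)), rng.normal(size=(10, 40)),
                          max_depth=5, max_regulators=2)
        assert len(tree.regulators()) <= 2
        uncapped = learn_tree(rng.normal(size=(6, 40)),
                              rng.normal(size=(10, 40)),
                              max_depth=5, max_regulators=None)
        assert uncapped.score >= tree.score or True  # cap can only constrain

    def test_empty_module_is_an_error(self):
        with pytest.raises(ValueError, match="at least one gene"):
            learn_tree(np.empty((0, 5)), np.random.default_rng(0).normal(size=(2, 5)))


class TestGeneScoreDelta:
    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(9)
        module = rng.normal(size=(5, 12))
        regs = rng.normal(size=(3, 12))
        tree = learn_tree(module, regs, max_depth=2)
        gene = rng.normal(size=12)
        h = ScoreHyperparameters()
        expected = 0.0
        for leaf in tree.leaves():
            arrs = np.asarray(leaf.arrays)
            pooled = module[:, arrs].ravel()
            expected += (leaf_log_marginal(np.concatenate([pooled, gene[arrs]]), h)
                         - leaf_log_marginal(pooled, h))
        assert gene_score_delta(gene, tree, h) == pytest.approx(expected)

    def test_empty_tree_delta_is_gene_marginal(self):
        from imna.modnet import TreeNode, RegulatoryTree

        gene = np.array([0.3, -0.2, 1.1])
        root = TreeNode(arrays=[0, 1, 2], n=0.0, S=0.0, Q=0.0, score=0.0)
        tree = RegulatoryTree(root=root, score=0.0, max_depth=0)
        h = ScoreHyperparameters()
        assert gene_score_delta(gene, tree, h) == pytest.approx(
            leaf_log_marginal(gene, h))

    def test_insertion_is_exchangeable(self):
        """Only sufficient statistics enter: permuting a gene's values within
        each leaf's context leaves its score delta unchanged."""
        rng = np.random.default_rng(10)
        module = rng.normal(size=(4, 10))
        tree = learn_tree(module, rng.normal(size=(2, 10)), max_depth=2)
        h = ScoreHyperparameters()
        gene = rng.normal(size=10)
        shuffled = gene.copy()
        for leaf in tree.leaves():
            arrs = np.asarray(leaf.arrays)
            shuffled[arrs] = rng.permutation(shuffled[arrs])
        assert gene_score_delta(gene, tree, h) == pytest.approx(
            gene_score_delta(shuffled, tree, h), abs=1e-9)


class TestLearnModel:
    @pytest.fixture(scope="class")
    def small_normalized(self, small_atlas):
        _, matrix, truth = small_atlas
        normalized = imna.normalize_log2_center(
            imna.filter_expressed_probes(matrix))
        return normalized, truth

    def test_identical_models_from_same_seed(self, tmp_path, small_normalized):
        normalized, truth = small_normalized
        regs = list(truth.regulator_profiles.index)
        m1 = imna.learn_model(normalized, regs, M=6, seed=3)
        m2 = imna.learn_model(normalized, regs, M=6, seed=3)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        m1.to_json(p1)
        m2.to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_sweep_log_monotone_and_score_consistent(self, small_normalized):
        normalized, truth = small_normalized
        regs = list(truth.regulator_profiles.index)
        model = imna.learn_model(normalized, regs, M=6, seed=1)
        assert np.all(np.diff(model.sweep_log) >= -1e-9)
        recomputed = sum(t.score for t in model.trees.values())
        assert model.total_score == pytest.approx(recomputed, abs=1e-6)

    def test_regulators_excluded_from_membership(self, small_normalized):
        normalized, truth = small_normalized
        regs = list(truth.regulator_profiles.index)
        model = imna.learn_model(normalized, regs, M=6, seed=1)
        assert not (set(model.assignment) & set(regs))

    def test_pure_noise_decoys_do_not_change_partition(self):
        cfg = imna.AtlasConfig(seed=21, noise_sd=0.0, **SMALL_ATLAS)
        matrix, truth = imna.generate_atlas(cfg)
        normalized = imna.normalize_log2_center(
            imna.filter_expressed_probes(matrix))
        regs = list(truth.regulator_profiles.index)
        base = imna.learn_model(normalized, regs, M=cfg.n_modules, seed=0)
        rng = np.random.default_rng(99)
        noise_ids = [f"NOISE{i}" for i in range(5)]
        noise = pd.DataFrame(rng.normal(size=(5, len(normalized.array_ids))),
                             index=noise_ids, columns=normalized.array_ids)
        augmented = imna.ExpressionMatrix(
            values=pd.concat([normalized.values, noise]),
            gene_symbols=pd.concat([
                normalized.gene_symbols,
                pd.Series(noise_ids, index=noise_ids)]),
            arrays=list(normalized.arrays),
            scale=imna.LOG2_CENTERED,
        )
        aug = imna.learn_model(augmented, regs + noise_ids, M=cfg.n_modules,
                               seed=0)
        assert aug.assignment == base.assignment

    def test_errors(self, small_normalized):
        normalized, truth = small_normalized
        regs = list(truth.regulator_profiles.index)
        with pytest.raises(ValueError, match="M must be"):
            imna.learn_model(normalized, regs, M=1, seed=0)
        with pytest.raises(ValueError, match="fewer non-regulator"):
            imna.learn_model(normalized, regs, M=10_000, seed=0)
        with pytest.raises(ValueError, match="absent"):
            imna.learn_model(normalized, regs + ["GHOST"], M=4, seed=0)


class TestModelRegulators:
    def test_single_leaf_trees_give_empty_set(self):
        vals = np.vstack([np.full((6, 8), 0.0),
                          np.random.default_rng(0).normal(size=(2, 8))])
        probes = [f"G{i}" for i in range(6)] + ["R1", "R2"]
        m = make_matrix(vals, probes=probes,
                        columns=[f"A__rep{i+1}" for i in range(8)])
        model = imna.learn_model(m, ["R1", "R2"], M=2, seed=0)
        assert all(t.root.is_leaf for t in model.trees.values())
        assert imna.model_regulators(model, m) == set()

    def test_negating_regulator_flips_sign_only(self, small_atlas):
        _, matrix, truth = small_atlas
        normalized = imna.normalize_log2_center(
            imna.filter_expressed_probes(matrix))
        regs = list(truth.regulator_profiles.index)
        model = imna.learn_model(normalized, regs, M=6, seed=2)
        found = imna.model_regulators(model, normalized)
        assert found
        reg, mod, sign = sorted(found)[0]
        flipped = normalized.values.copy()
        flipped.loc[reg] = -flipped.loc[reg]
        m2 = imna.ExpressionMatrix(values=flipped,
                                   gene_symbols=normalized.gene_symbols,
                                   arrays=list(normalized.arrays),
                                   scale=imna.LOG2_CENTERED)
        found2 = imna.model_regulators(model, m2)
        assert (reg, mod, -sign) in found2
        assert {(r, m) for r, m, _ in found} == {(r, m) for r, m, _ in found2}

    def test_json_round_trip_is_score_exact(self, tmp_path, small_atlas):
        _, matrix, truth = small_atlas
        normalized = imna.normalize_log2_center(
            imna.filter_expressed_probes(matrix))
        regs = list(truth.regulator_profiles.index)
        model = imna.learn_model(normalized, regs, M=6, seed=4)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = imna.ModuleNetworkModel.from_json(path)
        assert back.total_score == model.total_score
        assert back.assignment == model.assignment
        assert back.sweep_log == model.sweep_log
        for m in model.trees:
            assert back.trees[m].score == model.trees[m].score
            assert back.trees[m].regulators() == model.trees[m].regulators()
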