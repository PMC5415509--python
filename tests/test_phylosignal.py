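"""Brownian covariance, Pagel's lambda, Blomberg's K and ancestral states."""

import numpy as np
import pytest
from scipy.optimize import minimize

from morphotrace import (ancestral_continuous, blomberg_k, estimate_lambda,
                         lambda_transform, parse_newick, simulate_bm_trait,
                         simulate_yule_tree, vcv)
from morphotrace.phylosignal import PagelLambda

from conftest import random_tree_newick


def brute_force_vcv(tree):
    """Independent oracle: per-pair root-to-MRCA path walk."""
    d = tree.depths()
    labels = tree.tip_labels
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            mrca = tree.mrca([a, b]) if a != b else tree.tip(a)
            C[i, j] = d[mrca.id]
    return C, labels


class TestVcv:
    def test_star_tree_identity(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        C, _ = vcv(t)
        np.testing.assert_allclose(C, np.eye(4))

    def test_three_tip_path_sums(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        C, labels = vcv(t)
        i = {lab: k for k, lab in enumerate(labels)}
        assert C[i["A"], i["B"]] == pytest.approx(1.0)
        assert C[i["A"], i["A"]] == pytest.approx(2.0)
        assert C[i["A"], i["C"]] == pytest.approx(0.0)

    def test_matches_path_walk_oracle_on_random_trees(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            t = simulate_yule_tree(8, 1.0, seed=int(rng.integers(2**31)))
            C, labels = vcv(t)
            C2, labels2 = brute_force_vcv(t)
            assert labels == labels2
            np.testing.assert_allclose(C, C2, atol=1e-12)

    def test_missing_length_names_branch(self):
        t = parse_newick("((A:1,B:1),C:2);")
        with pytest.raises(Exception, match="branch"):
            vcv(t)


class TestLambdaTransform:
    def test_endpoint_and_midpoint_behaviour(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        C, labels = vcv(t)
        np.testing.assert_allclose(lambda_transform(C, 1.0), C)
        D = lambda_transform(C, 0.0)
        assert np.allclose(D, np.diag(np.diag(C)))
        i = {lab: k for k, lab in enumerate(labels)}
        assert lambda_transform(C, 0.5)[i["A"], i["B"]] == pytest.approx(0.5)

    def test_out_of_range_rejected(self):
        C = np.eye(3)
        with pytest.raises(ValueError):
            lambda_transform(C, 1.2)


class TestPagelLambda:
    def test_recovers_high_lambda_under_bm(self):
        t = simulate_yule_tree(200, 1.0, seed=123)
        trait = simulate_bm_trait(t, sigma2=1.0, lam=1.0, seed=456)
        est = estimate_lambda(t, trait)
        assert est.lambda_hat >= 0.9

    def test_shuffling_destroys_signal(self):
        t = simulate_yule_tree(200, 1.0, seed=123)
        trait = simulate_bm_trait(t, sigma2=1.0, lam=1.0, seed=456)
        rng = np.random.default_rng(789)
        labels = list(trait)
        vals = rng.permutation([trait[k] for k in labels])
        est = estimate_lambda(t, dict(zip(labels, vals)))
        assert est.lambda_hat <= 0.2

    def test_optimum_beats_grid(self):
        t = simulate_yule_tree(40, 1.0, seed=5)
        trait = simulate_bm_trait(t, sigma2=1.0, lam=0.6, seed=6)
        model = PagelLambda(t, trait)
        est = model.fit()
        grid = np.linspace(0, 1, 101)
        assert est.loglik >= max(model.loglik(l) for l in grid) - 1e-6

    def test_lambda0_equals_independent_normal_loglik(self):
        t = simulate_yule_tree(30, 1.0, seed=9)
        trait = simulate_bm_trait(t, sigma2=2.0, lam=1.0, seed=10)
        model = PagelLambda(t, trait)
        C, labels = vcv(t)
        y = np.array([trait[lab] for lab in model.labels])
        v = np.diag(model.C)
        # closed form: ML of independent normals with known relative
        # variances v_i, mean and scale profiled out
        mu = np.sum(y / v) / np.sum(1 / v)
        s2 = np.mean((y - mu) ** 2 / v)
        ll = -0.5 * (len(y) * np.log(2 * np.pi * s2) + np.sum(np.log(v))
                     + len(y))
        assert model.loglik(0.0) == pytest.approx(ll, abs=1e-8)

    def test_zero_variance_rejected(self):
        t = simulate_yule_tree(10, 1.0, seed=2)
        with pytest.raises(ValueError, match="variance"):
            estimate_lambda(t, {lab: 1.0 for lab in t.tip_labels})


class TestBlombergK:
    def test_matches_formula_chain_on_small_instance(self):
        t = parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        trait = {"A": 1.0, "B": 2.0, "C": 4.0, "D": 7.0}
        est = blomberg_k(t, trait)
        # independent spreadsheet-style recomputation
        C, labels = vcv(t)
        y = np.array([trait[lab] for lab in labels])
        Ci = np.linalg.inv(C)
        ones = np.ones(4)
        mu = ones @ Ci @ y / (ones @ Ci @ ones)
        mse0 = ((y - mu) ** 2).sum() / 3
        mse = (y - mu) @ Ci @ (y - mu) / 3
        expect = (np.trace(C) - 4 / (ones @ Ci @ ones)) / 3
        assert est.K == pytest.approx((mse0 / mse) / expect, abs=1e-12)

    def test_white_noise_deflates_k(self):
        t = simulate_yule_tree(100, 1.0, seed=31)
        rng = np.random.default_rng(32)
        ks = []
        for _ in range(30):
            trait = dict(zip(t.tip_labels, rng.standard_normal(100)))
            ks.append(blomberg_k(t, trait).K)
        assert np.mean(ks) < 0.7

    def test_permutation_p_small_for_strong_signal(self):
        t = simulate_yule_tree(60, 1.0, seed=41)
        trait = simulate_bm_trait(t, sigma2=1.0, lam=1.0, seed=42)
        est = blomberg_k(t, trait, n_permutations=199, seed=43)
        assert est.p_permutation < 0.05

    def test_permutation_requires_seed(self):
        t = simulate_yule_tree(10, 1.0, seed=2)
        trait = simulate_bm_trait(t, 1.0, seed=3)
        with pytest.raises(ValueError, match="seed"):
            blomberg_k(t, trait, n_permutations=10)


class TestAncestralContinuous:
    def test_constant_trait_constant_everywhere(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        est = ancestral_continuous(t, {k: 3.5 for k in "ABCD"})
        assert all(v == pytest.approx(3.5) for v in est.values())

    def test_two_tip_symmetric_average(self):
        t = parse_newick("(A:1,B:1);")
        est = ancestral_continuous(t, {"A": 0.0, "B": 2.0})
        assert est[t.root.id] == pytest.approx(1.0)

    def test_root_equals_gls_phylogenetic_mean(self):
        t = simulate_yule_tree(12, 1.0, seed=8)
        trait = simulate_bm_trait(t, 1.0, seed=9)
        est = ancestral_continuous(t, trait)
        C, labels = vcv(t)
        y = np.array([trait[lab] for lab in labels])
        Ci = np.linalg.inv(C)
        ones = np.ones(len(y))
        mu = ones @ Ci @ y / (ones @ Ci @ ones)
        assert est[t.root.id] == pytest.approx(mu, abs=1e-8)

    def test_matches_numeric_optimisation_oracle(self):
        t = simulate_yule_tree(8, 1.0, seed=77)
        trait = simulate_bm_trait(t, 1.0, seed=78)
        est = ancestral_continuous(t, trait)
        internal = [nd for nd in t.nodes if not nd.is_leaf]

        def cost(x):
            val = {nd.id: x[k] for k, nd in enumerate(internal)}
            for tip in t.tips:
                val[tip.id] = trait[tip.label]
            return sum((val[nd.id] - val[nd.parent.id]) ** 2 / nd.length
                       for nd in t.nodes if nd is not t.root)

        res = minimize(cost, np.zeros(len(internal)), method="BFGS",
                       options={"gtol": 1e-10})
        for k, nd in enumerate(internal):
            assert est[nd.id] == pytest.approx(res.x[k], abs=1e-6)


class TestInvariances:
    def test_likelihood_invariant_under_tree_isomorphic_relabelling(self):
        t = simulate_yule_tree(20, 1.0, seed=55)
        trait = simulate_bm_trait(t, 1.0, seed=56)
        m1 = PagelLambda(t, trait)
        # swap the label attachment consistently: rename tips and trait keys
        mapping = {lab: f"x_{lab}" for lab in t.tip_labels}
        t2 = t.copy()
        for tip in t2.tips:
            tip.label = mapping[tip.label]
        t2._index()
        trait2 = {mapping[k]: v for k, v in trait.items()}
        m2 = PagelLambda(t2, trait2)
        for lam in (0.0, 0.3, 1.0):
            assert m1.loglik(lam) == pytest.approx(m2.loglik(lam), abs=1e-9)
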