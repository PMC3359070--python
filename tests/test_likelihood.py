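"""Likelihood machinery: transition math, discrete gamma, pruning engine."""

import numpy as np
import pytest

from conftest import random_tree
from lbasim.alignment import Alignment
from lbasim.likelihood import (
    ModelSpec,
    PruningEngine,
    brute_force_log_likelihood,
    discrete_gamma_rates,
    jc_transition,
    tree_log_likelihood,
)
from lbasim.search import estimate_rate_parameters, optimize_branch_lengths
from lbasim.simulate import SimulationParams, evolve_alignment
from lbasim.trees import parse_newick

GAMMA_INV = ModelSpec(asrv_mode="gamma_inv", alpha=1.0, p_inv=0.3)


def random_alignment(labels, n_sites, rng):
    return Alignment(list(labels), rng.integers(0, 4, (len(labels), n_sites)))


class TestJCTransition:
    def test_zero_length_is_identity(self):
        assert np.allclose(jc_transition(0.0), np.eye(4))

    def test_saturation(self):
        assert np.allclose(jc_transition(1e3), np.full((4, 4), 0.25))

    def test_closed_form_at_t_01(self):
        p = jc_transition(0.1, rate=1.0)
        assert p[0, 0] == pytest.approx(0.906380, abs=1e-6)
        assert p[0, 1] == pytest.approx(0.031207, abs=1e-6)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_rate_scales_time(self):
        assert np.allclose(jc_transition(0.2, 0.5), jc_transition(0.1, 1.0))


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 2.0, 50.0])
    def test_unit_mean(self, alpha):
        rates = discrete_gamma_rates(alpha, 4)
        assert abs(rates.mean() - 1.0) < 1e-10
        assert np.all(np.diff(rates) > 0)

    def test_exponential_quartile_means(self):
        # alpha=1 is Exp(1): the interval mean of x e^-x over [a,b] has the
        # closed form (a+1)e^-a - (b+1)e^-b, an independent derivation
        bounds = [0.0] + [-np.log(1 - k / 4) for k in (1, 2, 3)] + [np.inf]
        expected = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            hi = 0.0 if np.isinf(b) else (b + 1) * np.exp(-b)
            expected.append(4 * ((a + 1) * np.exp(-a) - hi))
        assert np.allclose(discrete_gamma_rates(1.0, 4), expected, atol=1e-6)

    def test_large_alpha_approaches_homogeneity(self):
        # Gamma(100) has sd 0.1; quartile-interval means sit within about
        # 1.3 sd of 1, and tighten as alpha grows
        dev_100 = np.abs(discrete_gamma_rates(100.0, 4) - 1.0)
        dev_1000 = np.abs(discrete_gamma_rates(1000.0, 4) - 1.0)
        assert np.all(dev_100 < 0.15)
        assert np.all(dev_1000 < dev_100)

    def test_single_category(self):
        assert discrete_gamma_rates(0.7, 1) == pytest.approx([1.0])


class TestModelSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(asrv_mode="none", alpha=1.0)
        with pytest.raises(ValueError):
            ModelSpec(asrv_mode="gamma")
        with pytest.raises(ValueError):
            ModelSpec(asrv_mode="gamma", alpha=1.0, p_inv=0.3)
        with pytest.raises(ValueError):
            ModelSpec(asrv_mode="gamma_inv", alpha=1.0, p_inv=1.0)

    def test_estimate_flags(self):
        m = ModelSpec(asrv_mode="gamma_inv", alpha="estimate", p_inv=0.3)
        assert m.estimates_alpha and not m.estimates_p_inv


class TestPruning:
    def test_constant_column_zero_lengths(self):
        tree = parse_newick("(a:0,b:0,c:0);")
        aln = Alignment.from_strings([("a", "A"), ("b", "A"), ("c", "A")])
        res = tree_log_likelihood(tree, aln, ModelSpec())
        assert res.log_likelihood == pytest.approx(np.log(0.25), abs=1e-12)

    def test_two_taxon_single_site_closed_form(self):
        tree = parse_newick("(a:0.75,b:0);")
        aln = Alignment.from_strings([("a", "A"), ("b", "A")])
        res = tree_log_likelihood(tree, aln, ModelSpec())
        expect = 0.25 * (0.25 + 0.75 * np.exp(-1.0))
        assert res.log_likelihood == pytest.approx(np.log(expect), abs=1e-10)

    def test_per_site_sums_to_total_and_is_log_probability(self, rng):
        tree = random_tree(list("abcde"), rng)
        aln = random_alignment("abcde", 40, rng)
        res = tree_log_likelihood(tree, aln, GAMMA_INV)
        assert res.per_site.sum() == pytest.approx(res.log_likelihood, abs=1e-8)
        assert np.all(res.per_site <= 0)

    @pytest.mark.parametrize("model,overrides", [
        (ModelSpec(), {}),
        (ModelSpec(asrv_mode="gamma", alpha=100.0), {}),
        (GAMMA_INV, {}),
        (ModelSpec(asrv_mode="gamma", alpha="estimate"), {"alpha": 0.6}),
    ])
    def test_matches_brute_force(self, rng, model, overrides):
        for _ in range(6):
            n = int(rng.integers(4, 7))
            tree = random_tree([f"s{i}" for i in range(n)], rng)
            aln = random_alignment([f"s{i}" for i in range(n)], 25, rng)
            pruned = tree_log_likelihood(tree, aln, model, **overrides)
            brute = brute_force_log_likelihood(tree, aln, model, **overrides)
            assert abs(pruned.log_likelihood - brute) < 1e-8

    def test_rerooted_traversal_gives_same_likelihood(self, rng):
        n1 = "((a:0.1,b:0.2):0.05,(c:0.3,d:0.4):0.07);"
        n2 = "((a:0.1,b:0.2):0.12,c:0.3,d:0.4);"
        aln = random_alignment("abcd", 60, rng)
        l1 = tree_log_likelihood(parse_newick(n1), aln, GAMMA_INV).log_likelihood
        l2 = tree_log_likelihood(parse_newick(n2), aln, GAMMA_INV).log_likelihood
        assert abs(l1 - l2) < 1e-8

    def test_alpha_100_approximates_no_asrv(self, rng):
        tree = random_tree(list("abcde"), rng)
        aln = evolve_alignment(tree, SimulationParams(2000, 1.0, 0.3), rng)
        ll_none = tree_log_likelihood(tree, aln, ModelSpec()).log_likelihood
        ll_g100 = tree_log_likelihood(
            tree, aln, ModelSpec(asrv_mode="gamma", alpha=100.0)
        ).log_likelihood
        assert abs(ll_g100 - ll_none) / abs(ll_none) < 1e-3

    def test_taxon_mismatch_rejected(self, rng):
        tree = random_tree(list("abcd"), rng)
        aln = random_alignment("abce", 10, rng)
        with pytest.raises(ValueError, match="match"):
            tree_log_likelihood(tree, aln, ModelSpec())

    def test_brute_force_refuses_large_trees(self, rng):
        tree = random_tree([f"x{i}" for i in range(11)], rng)
        aln = random_alignment([f"x{i}" for i in range(11)], 5, rng)
        with pytest.raises(ValueError, match="8 internal"):
            brute_force_log_likelihood(tree, aln, ModelSpec())


class TestBranchOptimization:
    def test_never_decreases(self, rng):
        tree = random_tree(list("abcdef"), rng)
        aln = evolve_alignment(tree, SimulationParams(500, 1.0, 0.3), rng)
        before = tree_log_likelihood(tree, aln, GAMMA_INV).log_likelihood
        _, res = optimize_branch_lengths(tree, aln, GAMMA_INV)
        assert res.log_likelihood >= before - 1e-9

    def test_two_taxon_divergence_recovery(self, rng):
        n, t = 100_000, 0.3
        true = parse_newick(f"(a:{t},b:0);")
        aln = evolve_alignment(true, SimulationParams(n, alpha=1e9, p_inv=0.0), rng)
        start = parse_newick("(a:0.05,b:0.05);")
        fitted, _ = optimize_branch_lengths(start, aln, ModelSpec())
        p_exp = 0.75 * (1 - np.exp(-4 * t / 3))
        se_d = np.sqrt(p_exp * (1 - p_exp) / n) / (1 - 4 * p_exp / 3)
        assert abs(fitted.path_length("a", "b") - t) < 3 * se_d

    def test_identical_sequences_hit_lower_clamp(self):
        tree = parse_newick("(a:0.2,b:0.1,c:0.3);")
        aln = Alignment.from_strings([("a", "ACGT" * 20), ("b", "ACGT" * 20),
                                      ("c", "ACGT" * 20)])
        fitted, _ = optimize_branch_lengths(tree, aln, ModelSpec())
        for _, _, ln in fitted.edges():
            assert ln <= 1e-5  # at the lower clamp, to Brent's resolution


class TestParameterEstimation:
    def test_requires_a_free_parameter(self, rng):
        tree = random_tree(list("abcd"), rng)
        aln = random_alignment("abcd", 10, rng)
        with pytest.raises(ValueError, match="estimate"):
            estimate_rate_parameters(tree, aln, GAMMA_INV)

    def test_no_invariant_sites_recovered(self, rng):
        tree = random_tree(list("abcdef"), rng)
        aln = evolve_alignment(tree, SimulationParams(4000, 1.0, 0.0), rng)
        model = ModelSpec(asrv_mode="gamma_inv", alpha="estimate", p_inv="estimate")
        _, p_inv, _ = estimate_rate_parameters(tree, aln, model)
        assert p_inv <= 0.05

    def test_gamma_only_fit_compensates_with_lower_alpha(self, rng):
        tree = random_tree(list("abcdef"), rng)
        aln = evolve_alignment(tree, SimulationParams(5000, 1.0, 0.3), rng)
        alpha, p_inv, _ = estimate_rate_parameters(
            tree, aln, ModelSpec(asrv_mode="gamma", alpha="estimate")
        )
        assert p_inv is None
        assert alpha < 1.0

    def test_boundary_reported_as_such(self, rng):
        # homogeneous data drives alpha to the upper bound region
        tree = parse_newick("((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05);")
        aln = evolve_alignment(tree, SimulationParams(2000, alpha=1e9, p_inv=0.0),
                               rng)
        alpha, _, _ = estimate_rate_parameters(
            tree, aln, ModelSpec(asrv_mode="gamma", alpha="estimate")
        )
        assert alpha > 5.0


class TestEngineInternals:
    def test_sweep_matches_full_likelihood(self, rng):
        tree = random_tree(list("abcdefg"), rng)
        aln = evolve_alignment(tree, SimulationParams(800, 1.0, 0.3), rng)
        eng = PruningEngine(aln, GAMMA_INV)
        eng.set_tree(tree)
        ll_sweep = eng.sweep_branches()
        assert ll_sweep == pytest.approx(eng.log_likelihood(), abs=1e-6)

    def test_monotone_across_sweeps(self, rng):
        tree = random_tree(list("abcdef"), rng)
        aln = evolve_alignment(tree, SimulationParams(500, 1.0, 0.3), rng)
        eng = PruningEngine(aln, GAMMA_INV)
        eng.set_tree(tree)
        lls = [eng.sweep_branches() for _ in range(4)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))
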