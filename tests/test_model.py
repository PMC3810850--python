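"""PTP likelihood machinery: edge classes, rates, LRT, counting, enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptpdelim import (
    Delimitation,
    DegenerateDelimitationError,
    classify_edges,
    count_delimitations,
    enumerate_delimitations,
    estimate_rates,
    log_likelihood,
    lrt_pvalue,
    null_log_likelihood,
    parse_newick,
)
from ptpdelim.errors import CapExceededError, TreeValidationError

from conftest import (
    balanced,
    caterpillar,
    random_antichain,
    random_lengths,
    random_topology,
)


def roots_by_label(tree, labels):
    ids = {tree.label(n): n for n in tree.preorder()}
    return Delimitation(tree, {ids[lab] for lab in labels})


FIG_AMONG = sorted([0.15, 0.11, 0.14, 0.10, 0.10, 0.12])
FIG_WITHIN = sorted([0.01, 0.02, 0.015, 0.014, 0.03, 0.02])


class TestDelimitation:
    def test_antichain_violations_rejected(self, fig_tree):
        ids = {fig_tree.label(n): n for n in fig_tree.preorder()}
        with pytest.raises(TreeValidationError):
            Delimitation(fig_tree, {ids["A"], ids["D"]})  # nested roots
        with pytest.raises(TreeValidationError):
            Delimitation(fig_tree, {ids["A"]})  # B-side leaves uncovered

    def test_degenerate_flags(self, fig_tree):
        single = Delimitation(fig_tree, {fig_tree.root_id})
        assert single.is_single_species and single.is_degenerate
        allsing = Delimitation(fig_tree, set(fig_tree.leaf_ids))
        assert allsing.is_all_singletons and allsing.is_degenerate
        four = roots_by_label(fig_tree, {"C", "D", "E", "F"})
        assert not four.is_degenerate and four.n_species == 4

    def test_species_sets_and_speciation_nodes(self, fig_tree):
        d = roots_by_label(fig_tree, {"C", "D", "E", "F"})
        assert sorted(map(sorted, d.species_sets())) == [
            ["C"], ["d1", "d2"], ["e1", "e2"], ["f1", "f2"]
        ]
        assert sorted(fig_tree.label(n) for n in d.speciation_nodes()) == [
            "A", "B", "D", "E", "F", "R"
        ]


class TestClassifyEdges:
    def test_example_delimitation(self, fig_tree):
        among, within = classify_edges(
            fig_tree, roots_by_label(fig_tree, {"C", "D", "E", "F"})
        )
        assert sorted(among) == FIG_AMONG
        assert sorted(within) == FIG_WITHIN

    def test_all_singletons_has_empty_within(self, fig_tree):
        among, within = classify_edges(
            fig_tree, Delimitation(fig_tree, set(fig_tree.leaf_ids))
        )
        assert within == [] and len(among) == 12

    def test_two_species_delimitation(self, fig_tree):
        among, within = classify_edges(fig_tree, roots_by_label(fig_tree, {"A", "B"}))
        assert sorted(among) == [0.11, 0.15]
        assert len(within) == 10

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(3, 10))
    def test_edge_conservation(self, seed, n):
        rng = np.random.default_rng(seed)
        t = random_lengths(random_topology(n, rng), rng)
        d = random_antichain(t, rng)
        among, within = classify_edges(t, d)
        assert len(among) + len(within) == t.n_edges


class TestRates:
    def test_example_rates(self, fig_tree):
        lam1, lam2 = estimate_rates(FIG_AMONG, FIG_WITHIN)
        assert lam1 == pytest.approx(8.33, abs=0.005)
        assert lam2 == pytest.approx(55.05, abs=0.005)

    def test_unit_means(self):
        assert estimate_rates([1.0], [1.0]) == (1.0, 1.0)

    def test_arithmetic(self):
        lam1, lam2 = estimate_rates([0.2, 0.4], [0.05])
        assert lam1 == pytest.approx(1 / 0.3)
        assert lam2 == pytest.approx(20.0)

    def test_empty_class_rejected(self):
        with pytest.raises(DegenerateDelimitationError):
            estimate_rates([], [1.0])

    def test_zero_lengths_floored_not_infinite(self):
        lam1, _ = estimate_rates([0.0, 0.0], [1.0], epsilon=1e-10)
        assert math.isfinite(lam1) and lam1 == pytest.approx(1e10)


class TestLogLikelihood:
    def test_example_value(self, fig_tree):
        fit = log_likelihood(fig_tree, roots_by_label(fig_tree, {"C", "D", "E", "F"}))
        assert fit.logL == pytest.approx(24.77, abs=0.005)
        assert fit.k == 6 and fit.n == 12

    def test_unit_case_closed_form(self):
        # one edge per class, length 1: lam1 = lam2 = 1, logL = -2
        from ptpdelim import two_class_loglik
        lam1, lam2, logL = two_class_loglik([1.0], [1.0])
        assert (lam1, lam2) == (1.0, 1.0)
        assert logL == pytest.approx(-2.0)

    def test_fixed_rate_at_mle_matches_free_fit(self, fig_tree):
        d = roots_by_label(fig_tree, {"C", "D", "E", "F"})
        free = log_likelihood(fig_tree, d)
        fixed = log_likelihood(fig_tree, d, fixed_lambda1=free.lambda1)
        assert fixed.logL == pytest.approx(free.logL, abs=1e-10)
        assert fixed.lambda1_fixed

    def test_degenerate_needs_fixed_rate(self, fig_tree):
        single = Delimitation(fig_tree, {fig_tree.root_id})
        with pytest.raises(DegenerateDelimitationError):
            log_likelihood(fig_tree, single)
        fit = log_likelihood(fig_tree, single, fixed_lambda1=8.0)
        assert fit.k == 0 and fit.n == 12

    def test_mle_optimality_under_rate_perturbation(self, fig_tree):
        """The closed-form rates maximize the likelihood: +-10% perturbation
        of either rate strictly lowers it."""
        among, within = classify_edges(
            fig_tree, roots_by_label(fig_tree, {"C", "D", "E", "F"})
        )
        k, nk = len(among), len(within)
        sa, sw = sum(among), sum(within)
        lam1, lam2 = estimate_rates(among, within)

        def ll(l1, l2):
            return k * math.log(l1) - l1 * sa + nk * math.log(l2) - l2 * sw

        base = ll(lam1, lam2)
        for f in (0.9, 1.1):
            assert ll(lam1 * f, lam2) < base
            assert ll(lam1, lam2 * f) < base

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 2**31 - 1),
           c=st.floats(0.1, 10.0, allow_nan=False))
    def test_scale_covariance(self, seed, c):
        """Scaling all lengths by c divides both rates by c and shifts logL
        by exactly -n ln(c)."""
        rng = np.random.default_rng(seed)
        t = random_lengths(random_topology(7, rng), rng, scale=0.1)
        d = random_antichain(t, rng)
        fit = log_likelihood(t, d)
        t2 = t.scaled(c)
        fit2 = log_likelihood(t2, Delimitation(t2, d.species_roots))
        assert fit2.lambda1 == pytest.approx(fit.lambda1 / c, rel=1e-9)
        assert fit2.lambda2 == pytest.approx(fit.lambda2 / c, rel=1e-9)
        assert fit2.logL - fit.logL == pytest.approx(
            -fit.n * math.log(c), rel=1e-6, abs=1e-8
        )


class TestNull:
    def test_example_null_fit(self, fig_tree):
        lam, logL0 = null_log_likelihood(fig_tree)
        assert lam == pytest.approx(12 / 0.829, rel=1e-9)
        assert logL0 == pytest.approx(12 * math.log(12 / 0.829) - 12, rel=1e-9)
        assert logL0 == pytest.approx(20.069, abs=0.005)

    def test_two_unit_edges(self):
        lam, logL0 = null_log_likelihood(parse_newick("(a:1.0,b:1.0)r;"))
        assert lam == 1.0 and logL0 == pytest.approx(-2.0)

    def test_rate_recovery_on_simulated_edges(self):
        rng = np.random.default_rng(12345)
        lengths = rng.exponential(1 / 5.0, size=100)
        spec = (None, None, [(f"x{i}", float(v), []) for i, v in enumerate(lengths)])
        from ptpdelim import RootedTree
        lam, _ = null_log_likelihood(RootedTree.from_nested(spec))
        assert lam == pytest.approx(5.0, rel=0.15)


class TestLRT:
    def test_example_statistic(self, fig_tree):
        fit = log_likelihood(fig_tree, roots_by_label(fig_tree, {"C", "D", "E", "F"}))
        _, logL0 = null_log_likelihood(fig_tree)
        stat, p = lrt_pvalue(fit.logL, logL0)
        assert stat == pytest.approx(9.40, abs=0.005)
        assert p == pytest.approx(2.2e-3, rel=0.05)

    def test_equal_likelihoods(self):
        stat, p = lrt_pvalue(5.0, 5.0)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_quantile(self):
        _, p = lrt_pvalue(5.0 + 3.841 / 2, 5.0)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_float_noise_clamped(self):
        stat, p = lrt_pvalue(5.0 - 1e-12, 5.0)
        assert stat == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            lrt_pvalue(4.0, 5.0)


class TestCountAndEnumerate:
    def test_example_count_is_16(self, fig_tree):
        assert count_delimitations(fig_tree) == 16

    @pytest.mark.parametrize("m", range(3, 13))
    def test_caterpillar_attains_lower_bound(self, m):
        assert count_delimitations(caterpillar(m)) == m

    def test_balanced_counts_match_enumeration(self):
        # recursion: cherries 2, 4-leaf subtrees 5, 8-leaf root 1 + 5*5 = 26,
        # 16-leaf root 1 + 26*26 = 677; both confirmed by brute enumeration
        t8, t16 = balanced(3), balanced(4)
        assert count_delimitations(t8) == 26
        assert sum(1 for _ in enumerate_delimitations(t8)) == 26
        assert count_delimitations(t16) == 677
        assert sum(1 for _ in enumerate_delimitations(t16, cap=1000)) == 677

    def test_example_enumeration_distinct_and_complete(self, fig_tree):
        seen = {d.species_roots for d in enumerate_delimitations(fig_tree)}
        assert len(seen) == 16

    def test_cherry_enumeration(self):
        t = parse_newick("(a:1,b:1)r;")
        delims = list(enumerate_delimitations(t))
        assert len(delims) == 2
        kinds = {(d.is_single_species, d.is_all_singletons) for d in delims}
        assert kinds == {(True, False), (False, True)}

    def test_cap_refusal_names_count(self):
        t = balanced(5)  # 677**2 + 1 = 458330 delimitations
        with pytest.raises(CapExceededError) as exc:
            next(iter(enumerate_delimitations(t, cap=1000)))
        assert str(count_delimitations(t)) in str(exc.value)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 8))
    def test_enumeration_matches_count_on_random_trees(self, seed, n):
        rng = np.random.default_rng(seed)
        t = random_topology(n, rng)
        total = count_delimitations(t)
        delims = list(enumerate_delimitations(t))
        assert len(delims) == total
        assert len({d.species_roots for d in delims}) == total

    def test_multifurcating_count(self):
        t = parse_newick("((a:1,b:1,c:1)x:1,d:1)r;")
        # D(x) = 1 + 1*1*1 = 2; D(r) = 1 + 2*1 = 3
        assert count_delimitations(t) == 3
        assert sum(1 for _ in enumerate_delimitations(t)) == 3
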