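"""The per-edge SMC likelihood: ordering, profiles, closed forms, comparators."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import poisson

from argsmc import (
    ArgTables,
    LikelihoodEvaluator,
    arg_log_likelihood,
    arg_log_likelihood_piecewise,
    degree_log_factor,
    edge_coal_logterm,
    hazard_integral,
    kyf_log_likelihood,
    leftmost_flags,
    mutation_log_likelihood,
    overlap_profiles,
    piecewise_demography,
    simulate,
    squash_edges,
)
from argsmc.arg_core import StructuralError
from argsmc.smc_likelihood import (
    OverlapProfile,
    _log_integral_exp,
    edge_order_key,
    edge_total_order,
    eligible_links,
    event_exponents,
    mutations_per_edge,
)

from conftest import (
    FOUR_EDGE,
    brute_overlap_count,
    four_edge_hand_loglik,
    small_random_args,
)


class TestOrderingAndLinks:
    def test_order_key_rules(self):
        assert edge_order_key((9, 0, 0, 5)) < edge_order_key((8, 1, 0, 9))  # child tie-break
        assert edge_order_key((1, 3, 1, 2)) < edge_order_key((0, 2, 3, 9))  # left first

    def test_total_order_invariant_to_row_order(self, four_edge_arg):
        perm = np.array([2, 0, 3, 1])
        shuffled = ArgTables(
            node_time=four_edge_arg.node_time,
            node_flags=four_edge_arg.node_flags,
            edge_parent=four_edge_arg.edge_parent[perm],
            edge_child=four_edge_arg.edge_child[perm],
            edge_left=four_edge_arg.edge_left[perm],
            edge_right=four_edge_arg.edge_right[perm],
            sequence_length=four_edge_arg.sequence_length,
        )
        keys = lambda a: [
            (a.edge_left[i], a.edge_child[i]) for i in edge_total_order(a)
        ]
        assert keys(shuffled) == keys(four_edge_arg)

    def test_leftmost_one_per_child(self):
        for arg in small_random_args(5, base_seed=400):
            lm = leftmost_flags(arg)
            for c in np.unique(arg.edge_child):
                assert lm[arg.edge_child == c].sum() == 1

    def test_eligible_links_and_conservation(self):
        assert eligible_links((0, 1, 0, 100), True) == 100
        assert eligible_links((0, 1, 5, 6), False) == 0
        # child lineage split at x1: links sum to y - x0 - 1
        x0, x1, y = 0, 30, 90
        assert (
            eligible_links((0, 1, x0, x1), True)
            + eligible_links((0, 1, x1, y), False)
            == y - x0 - 1
        )


class TestOverlapProfiles:
    def test_four_edge_fixture_profiles(self, four_edge_arg):
        tu, tv = FOUR_EDGE["tu"], FOUR_EDGE["tv"]
        profs = overlap_profiles(four_edge_arg)
        # e0=(u,a,0,x): nothing earlier overlaps
        assert profs[0].counts.tolist() == [0]
        # e1=(u,b,0,L): e0 covers 0 throughout [0,tu)
        assert profs[1].breakpoints.tolist() == [0, tu] and profs[1].counts.tolist() == [1]
        # e2=(v,a,x,L): e1 covers x on [0,tu), nothing on [tu,tv)
        assert profs[2].breakpoints.tolist() == [0, tu, tv]
        assert profs[2].counts.tolist() == [1, 0]
        # e3=(v,u,x,L): e2 covers x on [tu,tv)
        assert profs[3].breakpoints.tolist() == [tu, tv] and profs[3].counts.tolist() == [1]

    def test_sweep_matches_brute_force_on_random_args(self):
        rng = np.random.default_rng(0)
        for arg in small_random_args(8, base_seed=200):
            profs = overlap_profiles(arg)
            for e, prof in enumerate(profs):
                lo, hi = prof.breakpoints[0], prof.breakpoints[-1]
                grid = np.concatenate(
                    [prof.breakpoints[:-1], rng.uniform(lo, hi, size=10)]
                )
                for t in grid:
                    i = np.searchsorted(prof.breakpoints, t, side="right") - 1
                    i = min(max(i, 0), len(prof.counts) - 1)
                    assert prof.counts[i] == brute_overlap_count(arg, e, t), (e, t)


class TestHazardIntegral:
    def test_constant_profile(self):
        prof = OverlapProfile(0, np.array([0.0, 3.0]), np.array([2]))
        assert hazard_integral(prof, 0.0, 3.0) == 6.0
        assert hazard_integral(prof, 1.0, 1.0) == 0.0

    def test_invalid_limits(self):
        prof = OverlapProfile(0, np.array([0.0, 3.0]), np.array([2]))
        with pytest.raises(Exception):
            hazard_integral(prof, 2.0, 1.0)

    @given(
        st.lists(st.floats(0.1, 9.9), min_size=0, max_size=4, unique=True),
        st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_riemann_sum(self, interior, seed):
        rng = np.random.default_rng(seed)
        pts = np.array(sorted([0.0, *interior, 10.0]))
        counts = rng.integers(0, 5, size=len(pts) - 1)
        prof = OverlapProfile(0, pts, counts)
        s, t = sorted(rng.uniform(0, 10, size=2))
        grid = np.linspace(s, t, 20001)
        mids = 0.5 * (grid[:-1] + grid[1:])
        idx = np.clip(np.searchsorted(pts, mids, side="right") - 1, 0, len(counts) - 1)
        riemann = float(np.sum(counts[idx] * np.diff(grid)))
        # the midpoint sum is exact except on the <=5 grid cells containing a
        # profile breakpoint, each off by at most (max count) * cell width
        bound = 5 * counts.max(initial=0) * (t - s) / 20000 + 1e-12
        assert abs(hazard_integral(prof, s, t) - riemann) <= bound


class TestCoalLogTerm:
    def test_leftmost_constant_profile(self):
        prof = OverlapProfile(0, np.array([0.0, 3.0]), np.array([2]))
        assert edge_coal_logterm(prof, True, r=1.0, lam=0.5) == pytest.approx(-3.0)

    def test_pure_exponential_integral(self):
        prof = OverlapProfile(0, np.array([0.0, 1.0]), np.array([0]))
        got = edge_coal_logterm(prof, False, r=1.0, lam=0.7, tp_prime=5.0)
        assert got == pytest.approx(np.log(1 - np.exp(-1.0)), rel=1e-12)

    def test_zero_rates_gives_log_interval_length(self):
        prof = OverlapProfile(0, np.array([2.0, 9.0]), np.array([3]))
        got = edge_coal_logterm(prof, False, r=0.0, lam=0.0, tp_prime=6.0)
        assert got == pytest.approx(np.log(6.0 - 2.0), rel=1e-12)

    def test_zero_length_edge_is_minus_inf(self):
        prof = OverlapProfile(0, np.array([3.0, 3.0]), np.array([0]))
        assert edge_coal_logterm(prof, True, 1.0, 1.0) == -np.inf
        assert edge_coal_logterm(prof, False, 1.0, 1.0, tp_prime=9.0) == -np.inf

    def test_closed_form_matches_quadrature_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            m = rng.integers(1, 5)
            pts = np.sort(rng.uniform(0, 10, size=m + 1))
            counts = rng.integers(0, 6, size=m)
            prof = OverlapProfile(0, pts, counts)
            r = rng.uniform(0, 2)
            lam = rng.uniform(0.01, 2)
            tp_prime = rng.uniform(pts[0], pts[-1] + 2)
            got = edge_coal_logterm(prof, False, r, lam, tp_prime=tp_prime)
            upper = min(pts[-1], tp_prime)
            if upper <= pts[0]:
                assert got == -np.inf
                continue

            # shift the exponent so quad works at sensible magnitudes even
            # when the integrand underflows double precision
            probe = np.linspace(pts[0], upper, 101)
            shift = min(
                r * s + lam * hazard_integral(prof, s, pts[-1]) for s in probe
            )

            def integrand(s):
                return np.exp(-r * s - lam * hazard_integral(prof, s, pts[-1]) + shift)

            # integrate between the integrand's kinks (profile breakpoints)
            knots = sorted({pts[0], upper, *(p for p in pts if pts[0] < p < upper)})
            val = sum(
                quad(integrand, a, b, limit=200)[0]
                for a, b in zip(knots[:-1], knots[1:])
            )
            want = np.log(val) - shift
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    @given(
        st.floats(-50, 50),
        st.floats(0, 20),
        st.floats(1e-6, 10),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_log_integral_exp_kernel(self, g, a, d):
        want = quad(lambda s: np.exp(g * (s - a)), a, a + d, limit=200)[0]
        got = _log_integral_exp(g, a, d) - g * a
        assert float(got) == pytest.approx(np.log(want), rel=1e-7, abs=1e-9)

    def test_degenerate_r_equals_lam_k(self):
        prof = OverlapProfile(0, np.array([0.0, 2.0]), np.array([1]))
        lam = 0.3
        got = edge_coal_logterm(prof, False, r=lam, lam=lam, tp_prime=10.0)
        # integrand is exp(-lam*2) constant in s
        assert got == pytest.approx(-lam * 2.0 + np.log(2.0), rel=1e-9)


class TestDegreeFactor:
    def test_hand_counts(self, two_sample_arg, four_edge_arg):
        assert degree_log_factor(two_sample_arg, 1.0, 1.0)[:2] == (0, 1)
        assert degree_log_factor(four_edge_arg, 1.0, 1.0)[:2] == (1, 2)

    def test_polytomy_contributes_squared_lambda(self):
        arg = ArgTables.build(
            [0.0, 0.0, 0.0, 5.0],
            [(3, 0, 0, 10), (3, 1, 0, 10), (3, 2, 0, 10)],
            10,
        )
        r_exp, lam_exp, value = degree_log_factor(arg, 1.0, 0.5)
        assert (r_exp, lam_exp) == (0, 2)
        assert value == pytest.approx(2 * np.log(0.5))

    def test_zero_rate_with_positive_exponent_warns(self, four_edge_arg):
        with pytest.warns(UserWarning):
            _, _, value = degree_log_factor(four_edge_arg, 0.0, 1.0)
        assert value == -np.inf


class TestFullLikelihood:
    def test_two_sample_closed_form(self, two_sample_arg):
        r, Ne = 1e-3, 50.0
        lam, t, L = 0.01, 7.3, 100
        res = arg_log_likelihood(two_sample_arg, r, Ne)
        assert res.log_likelihood == pytest.approx(
            np.log(lam) - lam * t - 2 * r * L * t, rel=1e-14
        )

    def test_four_edge_hand_derivation(self, four_edge_arg):
        r, lam = 1e-3, 0.01
        res = arg_log_likelihood(four_edge_arg, r, lam=lam)
        assert res.log_likelihood == pytest.approx(
            four_edge_hand_loglik(r, lam), abs=1e-12
        )
        assert (res.r_exponent, res.lambda_exponent) == (1, 2)

    def test_invariant_under_node_relabelling(self, four_edge_arg):
        # swap sample labels a<->b: permutes the child tie-break at left=0
        perm = np.array([1, 0, 2, 3])
        inv = np.argsort(perm)
        relabelled = ArgTables(
            node_time=four_edge_arg.node_time[perm],
            node_flags=four_edge_arg.node_flags[perm],
            edge_parent=inv[four_edge_arg.edge_parent],
            edge_child=inv[four_edge_arg.edge_child],
            edge_left=four_edge_arg.edge_left,
            edge_right=four_edge_arg.edge_right,
            sequence_length=four_edge_arg.sequence_length,
        )
        a = arg_log_likelihood(four_edge_arg, 1e-3, lam=0.01).log_likelihood
        b = arg_log_likelihood(relabelled, 1e-3, lam=0.01).log_likelihood
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_length_edge_gives_minus_inf(self):
        arg = ArgTables.build(
            [0.0, 0.0, 5.0, 5.0],
            [(2, 0, 0, 10), (2, 1, 0, 10), (3, 2, 0, 10)],
            10,
        )
        res = arg_log_likelihood(arg, 1e-3, 50.0)
        assert res.log_likelihood == -np.inf

    def test_unimodal_in_r_on_simulated_arg(self):
        arg, _ = simulate(10, 3000, 2e-4, 60.0, seed=77)
        ev = LikelihoodEvaluator(arg)
        grid = np.geomspace(2e-5, 2e-3, 25)
        ll = np.array([ev.log_likelihood(r, 60.0).log_likelihood for r in grid])
        diffs = np.sign(np.diff(ll))
        # increasing then decreasing: exactly one sign change
        changes = np.sum(diffs[:-1] != diffs[1:])
        assert changes == 1
        assert grid[np.argmax(ll)] not in (grid[0], grid[-1])

    def test_breakdown_reconstructs_total(self):
        arg, _ = simulate(6, 800, 3e-4, 40.0, seed=19)
        res = arg_log_likelihood(arg, 2e-4, 40.0, per_edge=True)
        total = (
            res.r_exponent * np.log(res.r)
            + res.lambda_exponent * np.log(res.lam)
            + sum(t.log_A + t.log_B for t in res.edge_terms)
        )
        assert total == pytest.approx(res.log_likelihood, rel=1e-12)

    def test_cosmetic_split_changes_value_and_squash_restores_it(self):
        canonical = ArgTables.build(
            [0.0, 0.0, 6.0], [(2, 0, 0, 100), (2, 1, 0, 100)], 100
        )
        split = ArgTables.build(
            [0.0, 0.0, 6.0], [(2, 0, 0, 40), (2, 0, 40, 100), (2, 1, 0, 100)], 100
        )
        want = arg_log_likelihood(canonical, 1e-3, 50.0).log_likelihood
        got_squash = arg_log_likelihood(squash_edges(split), 1e-3, 50.0).log_likelihood
        got_split = arg_log_likelihood(split, 1e-3, 50.0).log_likelihood
        assert got_squash == pytest.approx(want, rel=1e-12)
        assert got_split != pytest.approx(want, rel=1e-9)


class TestPiecewise:
    def test_single_piece_equals_plain_likelihood(self, four_edge_arg):
        demog = piecewise_demography([50.0])
        pw = arg_log_likelihood_piecewise(four_edge_arg, 1e-3, demog)
        plain = arg_log_likelihood(four_edge_arg, 1e-3, 50.0)
        assert pw.total == pytest.approx(plain.log_likelihood, rel=1e-14)

    def test_exact_when_integrals_avoid_boundaries(self, four_edge_arg):
        # the only breakpoint-time integral spans [0, tu] subset of slice 1
        T = FOUR_EDGE["tv"] + 1.0
        demog = piecewise_demography([50.0, 50.0], [T])
        # cut nothing in time support: slice above holds no edges -> exact
        pw = arg_log_likelihood_piecewise(four_edge_arg, 1e-3, demog)
        plain = arg_log_likelihood(four_edge_arg, 1e-3, 50.0)
        assert pw.total == pytest.approx(plain.log_likelihood, rel=1e-12)
        # boundary inside (tu, tv): e3's integral still confined to [0, tu]
        demog2 = piecewise_demography([50.0, 50.0], [0.5 * (FOUR_EDGE["tu"] + FOUR_EDGE["tv"])])
        pw2 = arg_log_likelihood_piecewise(four_edge_arg, 1e-3, demog2)
        assert pw2.total == pytest.approx(plain.log_likelihood, rel=1e-12)

    def test_exponent_bookkeeping_three_slices(self):
        arg, _ = simulate(8, 1200, 2e-4, 50.0, seed=29)
        demog = piecewise_demography([50.0, 30.0, 50.0], [30.0, 100.0])
        pw = arg_log_likelihood_piecewise(arg, 2e-4, demog)
        r_sum = sum(x.r_exponent for x in pw.per_slice)
        l_sum = sum(x.lambda_exponent for x in pw.per_slice)
        assert (r_sum, l_sum) == event_exponents(arg)

    def test_misaligned_spec_rejected(self, four_edge_arg):
        from argsmc import SliceSpec, ParameterError

        demog = piecewise_demography([50.0, 40.0], [5.0])
        with pytest.raises(ParameterError):
            arg_log_likelihood_piecewise(four_edge_arg, 1e-3, demog, spec=SliceSpec([4.0]))


class TestMutationLikelihood:
    def test_no_mutations_zero_rate(self, two_sample_arg):
        assert mutation_log_likelihood(two_sample_arg, mu=0.0) == 0.0

    def test_single_edge_poisson_term(self):
        arg = ArgTables.build(
            [0.0, 5.0], [(1, 0, 0, 2)], 2, mutations=[(0, 1)]
        )  # area = 2 * 5 = 10
        got = mutation_log_likelihood(arg, mu=0.1)
        assert got == pytest.approx(np.log(1.0) - 1.0)

    def test_matches_scipy_poisson_product(self):
        arg, _ = simulate(6, 500, 4e-4, 40.0, seed=51, mu=5e-4)
        mu = 5e-4
        counts = mutations_per_edge(arg)
        area = (arg.edge_right - arg.edge_left) * (
            arg.edge_parent_time - arg.edge_child_time
        )
        want = float(np.sum(poisson.logpmf(counts, mu * area)))
        assert mutation_log_likelihood(arg, mu=mu) == pytest.approx(want, rel=1e-12)

    def test_mutation_off_every_edge_is_structural_error(self):
        arg = ArgTables.build([0.0, 5.0], [(1, 0, 0, 2)], 4, mutations=[(0, 3)])
        with pytest.raises(StructuralError):
            mutations_per_edge(arg)


class TestKyfComparator:
    def test_two_sample_equals_per_edge_likelihood(self, two_sample_arg):
        r, Ne = 1e-3, 50.0
        assert kyf_log_likelihood(two_sample_arg, r, Ne) == pytest.approx(
            arg_log_likelihood(two_sample_arg, r, Ne).log_likelihood, rel=1e-12
        )

    def test_rejects_non_event_complete_arg(self, four_edge_arg):
        # node a has parents at two different times: recombination node missing
        with pytest.raises(StructuralError):
            kyf_log_likelihood(four_edge_arg, 1e-3, 50.0)

    def test_r_dependence_identical_on_full_arg(self):
        arg, events = simulate(12, 5000, 2e-4, 60.0, seed=3)
        n_re = sum(1 for e in events if e.kind == "RE")
        ev = LikelihoodEvaluator(arg)
        assert ev.r_exponent == n_re
        grid = np.geomspace(5e-5, 8e-4, 9)
        eq5 = np.array([ev.log_likelihood(r, 60.0).log_likelihood for r in grid])
        kyf = np.array([kyf_log_likelihood(arg, r, 60.0) for r in grid])
        ratio_eq5 = eq5 - eq5[4]
        ratio_kyf = kyf - kyf[4]
        # identical r-exponent and A-terms; only the breakpoint-time integrals
        # carry extra r-dependence, a small correction on the curve scale
        # (tighter at realistic genome lengths; see the acceptance suite)
        scale = np.ptp(ratio_eq5)
        assert np.max(np.abs(ratio_eq5 - ratio_kyf)) < 0.05 * scale
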