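"""Unit tests for the MaxEnt core: beta relation, multiplier solving,
structure-function evaluation and the inner metabolic-rate integrals."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from ecostate import (
    DomainError,
    StateVariables,
    sample_structure_function,
    solve_beta_approx,
    solve_lagrange,
    structure_function,
)
from ecostate.mete_core import (
    BETA_MAX,
    approximate_lagrange,
    beta_from_ratio,
    eps_integral,
    log_normalization,
    mean_abundance,
    mean_energy_flux,
    sample_conditional_eps,
)


def bisect_beta(ratio, iters=200):
    """Independent bisection oracle for beta*ln(1/beta) = ratio on (0, 1/e)."""
    lo, hi = 1e-12, 1.0 / math.e
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid * math.log(1.0 / mid) < ratio:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestBetaApprox:
    def test_forward_constructed_root(self):
        # forward-evaluate the relation at beta = 0.01, then invert
        ratio = 0.01 * math.log(100.0)
        assert beta_from_ratio(ratio) == pytest.approx(0.01, rel=1e-10)

    def test_against_bisection_oracle(self):
        sv = StateVariables(16, 64, 640)  # S/N = 0.25
        beta = solve_beta_approx(sv)
        assert beta == pytest.approx(bisect_beta(0.25), rel=1e-9)
        assert abs(beta * math.log(1 / beta) - 0.25) / 0.25 <= 1e-10

    def test_monotone_to_zero_on_ascending_branch(self):
        ratios = np.logspace(-1, -8, 12)
        betas = [beta_from_ratio(r) for r in ratios]
        assert all(b2 < b1 for b1, b2 in zip(betas, betas[1:]))
        assert betas[-1] < 1e-7

    def test_infeasible_ratio_raises(self):
        with pytest.raises(DomainError, match="1/e"):
            beta_from_ratio(BETA_MAX * 1.01)
        with pytest.raises(DomainError):
            solve_beta_approx(StateVariables(40, 100, 1000))  # S/N = 0.4 > 1/e


class TestStateVariables:
    @pytest.mark.parametrize("s,n,e", [(1.5, 100, 1000), (10, 10, 1000),
                                       (10, 100, 100), (10, 5, 1000)])
    def test_degenerate_triples_rejected(self, s, n, e):
        with pytest.raises(DomainError):
            StateVariables(s, n, e)

    def test_real_valued_state_variables_accepted(self):
        sv = StateVariables(10.5, 1050.7, 26000.2)
        assert sv.n_max == 1050


class TestSolveLagrange:
    def test_constraint_roundtrip(self, triples):
        for sv in triples:
            sol = solve_lagrange(sv, tol=1e-10)
            assert sol.method == "exact_root"
            assert abs(sol.residual_n) <= 1e-10
            assert abs(sol.residual_e) <= 1e-10
            # definitional round trip through independent moment evaluation
            assert sv.S * mean_abundance(sol, sv) == pytest.approx(sv.N, rel=1e-9)
            assert sv.S * mean_energy_flux(sol, sv) == pytest.approx(sv.E, rel=1e-9)

    def test_beta_is_sum_of_multipliers_and_z_consistent(self):
        sv = StateVariables(10, 1000, 25000)
        sol = solve_lagrange(sv)
        assert sol.beta == sol.lambda1 + sol.lambda2
        assert sol.log_Z == pytest.approx(
            log_normalization(sol.lambda1, sol.lambda2, sv), rel=1e-12)

    def test_approximation_is_labelled(self):
        sol = approximate_lagrange(StateVariables(30, 3000, 1e5))
        assert sol.method == "approximation"

    def test_moments_match_monte_carlo(self, rng):
        sv = StateVariables(20, 2000, 1e5)
        sol = solve_lagrange(sv)
        n, eps = sample_structure_function(sol, sv, 10**6, rng)
        for sample, target in ((n, sv.N / sv.S), (n * eps, sv.E / sv.S)):
            se = sample.std(ddof=1) / math.sqrt(len(sample))
            assert abs(sample.mean() - target) <= 3 * se

    def test_asymptotic_agreement_with_beta_relation(self):
        # the closed beta relation becomes exact as S and N/S grow together
        gaps = []
        for s, ns, en in [(10, 50, 50), (30, 200, 100), (100, 1000, 200)]:
            sv = StateVariables(s, s * ns, s * ns * en)
            gaps.append(abs(solve_beta_approx(sv) / solve_lagrange(sv).beta - 1))
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3


class TestStructureFunction:
    def test_normalizes_to_one_against_quadrature(self):
        sv = StateVariables(6, 60, 600)
        sol = solve_lagrange(sv)
        total = sum(
            integrate.quad(lambda e, k=k: structure_function(k, e, sol, sv),
                           1.0, sv.E, limit=400)[0]
            for k in range(1, sv.n_max + 1))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_decreasing_in_n_at_fixed_eps(self):
        sv = StateVariables(10, 1000, 25000)
        sol = solve_lagrange(sv)
        eps = 5.0
        vals = [structure_function(k, eps, sol, sv) for k in (1, 5, 50, 500)]
        if sol.lambda1 + sol.lambda2 * eps > 0:
            assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_arguments_outside_support_raise(self):
        sv = StateVariables(10, 100, 1000)
        sol = solve_lagrange(sv)
        with pytest.raises(DomainError):
            structure_function(0, 5.0, sol, sv)
        with pytest.raises(DomainError):
            structure_function(101, 5.0, sol, sv)
        with pytest.raises(DomainError):
            structure_function(5, 0.5, sol, sv)
        with pytest.raises(DomainError):
            structure_function(5, sv.E * 1.1, sol, sv)

    def test_conditional_eps_is_truncated_exponential(self):
        # R(n, .) / marginal(n) == truncated exponential(rate lambda2*n) on [1, E]
        sv = StateVariables(10, 1000, 25000)
        sol = solve_lagrange(sv)
        n = 7
        a = sol.lambda2 * n
        marginal = eps_integral(n, 0.0, sol, sv) * math.exp(
            -sol.lambda1 * n - sol.log_Z)
        dist = stats.truncexpon(b=a * (sv.E - 1.0), loc=1.0, scale=1.0 / a)
        for eps in (1.0, 2.5, 10.0, 100.0):
            cond = structure_function(n, eps, sol, sv) / marginal
            assert cond == pytest.approx(dist.pdf(eps), rel=1e-9)

    def test_conditional_sampler_matches_distribution(self, rng):
        sv = StateVariables(10, 1000, 25000)
        sol = solve_lagrange(sv)
        n = 12
        draws = sample_conditional_eps(np.full(20000, n), sol, sv, rng)
        a = sol.lambda2 * n
        dist = stats.truncexpon(b=a * (sv.E - 1.0), loc=1.0, scale=1.0 / a)
        assert stats.kstest(draws, dist.cdf).pvalue > 0.01


class TestEpsIntegral:
    def test_power_zero_elementary_form(self):
        sv = StateVariables(10, 100, 1000)
        sol = solve_lagrange(sv)
        for n in (1, 7, 50):
            a = sol.lambda2 * n
            expected = (math.exp(-a) - math.exp(-a * sv.E)) / a
            assert eps_integral(n, 0.0, sol, sv) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("power", [1.0, 4.0 / 3.0, 1.5])
    def test_agrees_with_adaptive_quadrature(self, power):
        sv = StateVariables(10, 1000, 25000)
        sol = solve_lagrange(sv)
        for n in (1, 10, 100, 1000):
            closed = eps_integral(n, power, sol, sv)
            quad, _ = integrate.quad(
                lambda e: e**power * math.exp(-sol.lambda2 * n * e),
                1.0, sv.E, limit=500)
            assert closed == pytest.approx(quad, rel=1e-8)

    def test_consistency_check_mode_passes(self):
        sv = StateVariables(10, 1000, 25000)
        sol = solve_lagrange(sv)
        # check=True raises ConsistencyError on disagreement; should be silent
        eps_integral(10, 4.0 / 3.0, sol, sv, check=True)

    def test_vanishing_support(self):
        # as the upper limit E -> 1+, the integral shrinks to
        # eps^p e^(-a eps) |_{eps=1} * (E - 1) -> 0
        from ecostate.mete_core import _log_eps_integral
        for width in (1e-6, 1e-8):
            val = math.exp(float(_log_eps_integral(1.0, 4.0 / 3.0,
                                                   1.0 + width)))
            assert val == pytest.approx(math.exp(-1.0) * width, rel=1e-5)

    def test_invalid_arguments(self):
        sv = StateVariables(10, 100, 1000)
        sol = solve_lagrange(sv)
        with pytest.raises(DomainError):
            eps_integral(0, 1.0, sol, sv)
        with pytest.raises(DomainError):
            eps_integral(5, -1.0, sol, sv)
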