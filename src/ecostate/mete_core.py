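"""MaxEnt core of the ecological equation of state.

The ecosystem structure function ``R(n, eps | S, N, E)`` is the joint
probability that a randomly chosen species has abundance ``n`` and that a
randomly chosen individual of an ``n``-abundant species has metabolic rate in
``(eps, eps + d eps)``.  Maximizing Shannon entropy subject to the two moment
constraints

    S * <n>     = N        (mean abundance per species)
    S * <n eps> = E        (mean metabolic flux per species)

yields the Gibbs form ``R = exp(-lambda1 * n - lambda2 * n * eps) / Z`` with
Lagrange multipliers ``lambda1``, ``lambda2`` and normalization ``Z``.  This
module solves for the multipliers exactly (2-D root finding on the constraint
equations, seeded from the classical approximations ``beta ln(1/beta) = S/N``
and ``lambda2 = S/(E-N)``), evaluates ``R`` and its moments, and samples from
it.

Support conventions: abundance runs over the integers ``1..floor(N)``;
metabolic rate over the interval ``[1, E]``, reflecting the units convention
that the smallest metabolic rate in a plot is assigned the value 1.

All sums are evaluated in log-space so that communities with very large ``N``
or steep multipliers neither overflow nor silently lose the tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "DomainError",
    "SolverError",
    "ConsistencyError",
    "StateVariables",
    "LagrangeSolution",
    "solve_beta_approx",
    "beta_from_ratio",
    "approximate_lagrange",
    "solve_lagrange",
    "structure_function",
    "eps_integral",
    "joint_moment",
    "mean_abundance",
    "mean_energy_flux",
    "log_normalization",
    "abundance_pmf",
    "sample_structure_function",
    "sample_conditional_eps",
]

BETA_MAX = 1.0 / math.e  # supremum of x*ln(1/x) on (0, 1); feasibility bound on S/N


class DomainError(ValueError):
    """Raised when inputs violate the mathematical domain of an operation."""


class SolverError(RuntimeError):
    """Raised when root finding fails to meet the requested tolerance."""

    def __init__(self, message: str, residual_n: float = math.nan,
                 residual_e: float = math.nan):
        super().__init__(message)
        self.residual_n = residual_n
        self.residual_e = residual_e


class ConsistencyError(RuntimeError):
    """Raised when two independent evaluation routes disagree beyond tolerance."""


@dataclass(frozen=True)
class StateVariables:
    """Macro-level state of a community: richness S, abundance N, metabolism E.

    ``E`` is dimensionless under the units convention that the smallest
    individual metabolic rate equals 1.  ``S`` and ``N`` are accepted as
    positive reals so intensive-ratio studies are expressible; census-derived
    values are integers.
    """

    S: float
    N: float
    E: float

    def __post_init__(self):
        for name in ("S", "N", "E"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v!r}")
        if self.S < 2:
            raise DomainError(f"require S >= 2 (got S={self.S}); "
                              "the MaxEnt constraints degenerate below two species")
        if self.N <= self.S:
            raise DomainError(f"require N > S (got N={self.N}, S={self.S})")
        if self.E <= self.N:
            raise DomainError(f"require E > N (got E={self.E}, N={self.N}); "
                              "every individual has metabolic rate >= 1")

    @property
    def n_max(self) -> int:
        """Upper limit of the abundance sum."""
        return int(math.floor(self.N))


@dataclass(frozen=True)
class LagrangeSolution:
    """Fitted multipliers of the structure function for one (S, N, E) triple."""

    lambda1: float
    lambda2: float
    log_Z: float
    residual_n: float
    residual_e: float
    method: str  # "exact_root" | "approximation"

    @property
    def beta(self) -> float:
        return self.lambda1 + self.lambda2

    @property
    def Z(self) -> float:
        return math.exp(self.log_Z)

    def to_record(self) -> dict:
        """Flat key-value form for machine-readable output."""
        return {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "beta": self.beta,
            "log_Z": self.log_Z,
            "residual_n": self.residual_n,
            "residual_e": self.residual_e,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# beta approximation
# ---------------------------------------------------------------------------

def beta_from_ratio(s_over_n: float, rtol: float = 1e-12) -> float:
    """Solve ``beta * ln(1/beta) = S/N`` on the ascending branch (0, 1/e)."""
    r = float(s_over_n)
    if not 0.0 < r < BETA_MAX:
        raise DomainError(
            f"beta ln(1/beta) = S/N requires 0 < S/N < 1/e ≈ {BETA_MAX:.4f}; "
            f"got S/N = {r}")
    beta = optimize.brentq(lambda b: b * math.log(1.0 / b) - r,
                           1e-300, BETA_MAX, xtol=1e-300, rtol=4 * np.finfo(float).eps)
    resid = abs(beta * math.log(1.0 / beta) - r) / r
    if resid > rtol:
        raise SolverError(f"beta root residual {resid:.2e} exceeds {rtol:.1e}")
    return beta


def solve_beta_approx(sv: StateVariables) -> float:
    """The classical closed-relation estimate of beta = lambda1 + lambda2."""
    return beta_from_ratio(sv.S / sv.N)


# ---------------------------------------------------------------------------
# inner metabolic-rate integrals
# ---------------------------------------------------------------------------

def _log_eps_integral(a, power: float, E: float):
    """log of ``J_p(a) = int_1^E eps^p exp(-a*eps) d eps`` for a > 0, p >= 0.

    Closed form in regularized incomplete gamma functions,
    ``J_p = Gamma(p+1) a^{-(p+1)} [P(p+1, aE) - P(p+1, a)]``,
    switching to the upper-tail difference when both ``P`` values are near 1,
    and to a Watson-lemma tail expansion when the difference underflows.
    """
    a = np.asarray(a, dtype=float)
    s = power + 1.0
    Pa = special.gammainc(s, a)
    delta = np.where(Pa < 0.5,
                     special.gammainc(s, a * E) - Pa,
                     special.gammaincc(s, a) - special.gammaincc(s, a * E))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = special.gammaln(s) - s * np.log(a) + np.log(delta)
    bad = ~np.isfinite(out)
    if np.any(bad):
        # a so large that the gamma tail underflows: J_p ~ e^{-a}/a (1 + p/a + ...)
        ab = a[bad] if a.ndim else a
        tail = -ab - np.log(ab) + np.log1p(power / ab + power * (power - 1.0) / ab ** 2)
        if a.ndim:
            out[bad] = tail
        else:
            out = tail
    return out


def eps_integral(n: int, power: float, sol: LagrangeSolution,
                 sv: StateVariables, check: bool = False) -> float:
    """``int_1^E eps^power exp(-lambda2 * n * eps) d eps``.

    Uses the incomplete-gamma closed form; falls back to adaptive quadrature
    when that route underflows.  With ``check=True`` the closed form is
    verified against quadrature and a :class:`ConsistencyError` is raised on
    disagreement beyond 1e-6 relative.
    """
    if power < 0:
        raise DomainError(f"power must be >= 0, got {power}")
    if not 1 <= n <= sv.N:
        raise DomainError(f"n must lie in [1, N={sv.N}], got {n}")
    a = sol.lambda2 * n
    if a <= 0:
        raise DomainError(f"lambda2 * n must be positive, got {a}")
    log_j = float(_log_eps_integral(a, power, sv.E))
    closed = math.exp(log_j) if log_j > -745.0 else 0.0

    def _quad() -> float:
        val, _ = integrate.quad(lambda e: e ** power * math.exp(-a * e),
                                1.0, sv.E, limit=500)
        return val

    if not math.isfinite(closed):
        return _quad()
    if check:
        q = _quad()
        if q > 0 and abs(closed - q) / q > 1e-6:
            raise ConsistencyError(
                f"closed-form eps integral {closed:.12e} disagrees with "
                f"quadrature {q:.12e} (n={n}, power={power})")
    return closed


# ---------------------------------------------------------------------------
# moments of R via log-space summation over n
# ---------------------------------------------------------------------------

_CHUNK = 1 << 16


def _log_moment_sum(lambda1: float, lambda2: float, sv: StateVariables,
                    eps_power: float, n_power: float) -> float:
    """log of ``sum_{n=1}^{n_max} n^k exp(-lambda1 n) J_p(lambda2 n)``."""
    n_max = sv.n_max

    def chunk_logs(lo: int, hi: int):
        n = np.arange(lo, hi + 1, dtype=float)
        logs = -lambda1 * n + _log_eps_integral(lambda2 * n, eps_power, sv.E)
        if n_power != 0.0:
            logs += n_power * np.log(n)
        return logs

    if n_max <= 4 * _CHUNK:
        return float(special.logsumexp(chunk_logs(1, n_max)))

    total = -math.inf
    lo = 1
    while lo <= n_max:
        hi = min(lo + _CHUNK - 1, n_max)
        logs = chunk_logs(lo, hi)
        total = np.logaddexp(total, special.logsumexp(logs))
        # terminate once a decreasing tail contributes below 1e-16 of the total
        if logs[-1] < logs[0] and logs.max() < total + math.log(1e-16):
            break
        lo = hi + 1
    return float(total)


def _constraint_means(lambda1: float, lambda2: float,
                      sv: StateVariables) -> tuple[float, float, float]:
    """Return (log Z, <n>, <n eps>) for the given multipliers."""
    log_z = _log_moment_sum(lambda1, lambda2, sv, 0.0, 0.0)
    mean_n = math.exp(_log_moment_sum(lambda1, lambda2, sv, 0.0, 1.0) - log_z)
    mean_ne = math.exp(_log_moment_sum(lambda1, lambda2, sv, 1.0, 1.0) - log_z)
    return log_z, mean_n, mean_ne


def joint_moment(sol: LagrangeSolution, sv: StateVariables,
                 n_power: float = 1.0, eps_power: float = 0.0) -> float:
    """``< n^k eps^p >`` over R — the building block of every prediction."""
    return math.exp(
        _log_moment_sum(sol.lambda1, sol.lambda2, sv, eps_power, n_power)
        - sol.log_Z)


def mean_abundance(sol: LagrangeSolution, sv: StateVariables) -> float:
    return joint_moment(sol, sv, 1.0, 0.0)


def mean_energy_flux(sol: LagrangeSolution, sv: StateVariables) -> float:
    return joint_moment(sol, sv, 1.0, 1.0)


def log_normalization(lambda1: float, lambda2: float, sv: StateVariables) -> float:
    """log Z for arbitrary multipliers (not necessarily solved ones)."""
    return _log_moment_sum(lambda1, lambda2, sv, 0.0, 0.0)


# ---------------------------------------------------------------------------
# multiplier solving
# ---------------------------------------------------------------------------

def approximate_lagrange(sv: StateVariables) -> LagrangeSolution:
    """The literature seed: beta from ``beta ln(1/beta)=S/N``, lambda2=S/(E-N)."""
    beta = solve_beta_approx(sv)
    lambda2 = sv.S / (sv.E - sv.N)
    lambda1 = beta - lambda2
    log_z, mean_n, mean_ne = _constraint_means(lambda1, lambda2, sv)
    return LagrangeSolution(
        lambda1=lambda1, lambda2=lambda2, log_Z=log_z,
        residual_n=mean_n * sv.S / sv.N - 1.0,
        residual_e=mean_ne * sv.S / sv.E - 1.0,
        method="approximation")


def _residuals(lambda1: float, lambda2: float, sv: StateVariables):
    log_z, mean_n, mean_ne = _constraint_means(lambda1, lambda2, sv)
    return log_z, mean_n * sv.S / sv.N - 1.0, mean_ne * sv.S / sv.E - 1.0


def _nested_solve(sv: StateVariables, seed1: float, seed2: float,
                  tol: float) -> tuple[float, float]:
    """Bracketed nested 1-D solves: outer on lambda1, inner on log lambda2."""

    def lambda2_for(lambda1: float) -> float:
        # S*<n eps> is decreasing in lambda2 at fixed lambda1
        f = lambda t: _residuals(lambda1, math.exp(t), sv)[2]
        t0 = math.log(seed2)
        f0 = f(t0)
        step = 1.0
        t_lo, t_hi = t0, t0
        if f0 > 0:  # need larger lambda2
            while f0 > 0:
                t_lo, t_hi = t_hi, t_hi + step
                f0 = f(t_hi)
                step *= 2.0
                if t_hi > 700:
                    raise SolverError("no lambda2 bracket (upper)")
        else:
            while f0 <= 0:
                t_hi, t_lo = t_lo, t_lo - step
                f0 = f(t_lo)
                step *= 2.0
                if t_lo < -700:
                    raise SolverError("no lambda2 bracket (lower)")
        t = optimize.brentq(f, t_lo, t_hi, xtol=1e-14, rtol=4 * np.finfo(float).eps)
        return math.exp(t)

    def g(lambda1: float) -> float:
        return _residuals(lambda1, lambda2_for(lambda1), sv)[1]

    # S*<n> decreases as lambda1 grows; expand a bracket around the seed
    scale = max(abs(seed1), seed2, 1e-6)
    g0 = g(seed1)
    step = scale
    lo, hi = seed1, seed1
    if g0 > 0:  # need larger lambda1
        while g0 > 0:
            lo, hi = hi, hi + step
            g0 = g(hi)
            step *= 2.0
            if hi > 1e6:
                raise SolverError("no lambda1 bracket (upper)")
    else:
        while g0 <= 0:
            hi, lo = lo, lo - step
            g0 = g(lo)
            step *= 2.0
            if lo < -1e6:
                raise SolverError("no lambda1 bracket (lower)")
    lambda1 = optimize.brentq(g, lo, hi, xtol=1e-15, rtol=4 * np.finfo(float).eps)
    return lambda1, lambda2_for(lambda1)


@lru_cache(maxsize=512)
def _solve_lagrange_cached(sv: StateVariables, tol: float) -> LagrangeSolution:
    seed = approximate_lagrange(sv)
    seed2 = max(seed.lambda2, 1e-300)

    def fun(x):
        _, rn, re_ = _residuals(x[0], math.exp(x[1]), sv)
        return [rn, re_]

    best = None
    res = optimize.root(fun, [seed.lambda1, math.log(seed2)],
                        method="hybr", options={"xtol": 1e-13})
    lambda1, lambda2 = res.x[0], math.exp(res.x[1])
    log_z, rn, re_ = _residuals(lambda1, lambda2, sv)
    best = (lambda1, lambda2, log_z, rn, re_)

    if max(abs(rn), abs(re_)) > tol:
        lambda1, lambda2 = _nested_solve(sv, seed.lambda1, seed2, tol)
        log_z, rn, re_ = _residuals(lambda1, lambda2, sv)
        if max(abs(rn), abs(re_)) > max(abs(best[3]), abs(best[4])):
            lambda1, lambda2, log_z, rn, re_ = best

    if max(abs(rn), abs(re_)) > tol:
        raise SolverError(
            f"Lagrange solve did not reach tol={tol:.1e} for {sv}; "
            f"best residuals ({rn:.2e}, {re_:.2e})",
            residual_n=rn, residual_e=re_)
    return LagrangeSolution(lambda1=lambda1, lambda2=lambda2, log_Z=log_z,
                            residual_n=rn, residual_e=re_, method="exact_root")


def solve_lagrange(sv: StateVariables, tol: float = 1e-10) -> LagrangeSolution:
    """Find exact Lagrange multipliers so both constraints hold to ``tol``.

    A seeded 2-D quasi-Newton root is tried first; if it misses the tolerance,
    nested bracketed 1-D solves (outer on lambda1 via the abundance constraint,
    inner on lambda2 via the energy constraint) take over.  The returned
    solution always carries verified relative residuals.
    """
    return _solve_lagrange_cached(sv, float(tol))


# ---------------------------------------------------------------------------
# evaluation and sampling
# ---------------------------------------------------------------------------

def structure_function(n, eps, sol: LagrangeSolution, sv: StateVariables):
    """Density ``R(n, eps | S, N, E)`` on the support {1..N} x [1, E]."""
    n_arr = np.asarray(n, dtype=float)
    e_arr = np.asarray(eps, dtype=float)
    if np.any(n_arr < 1) or np.any(n_arr > sv.n_max):
        raise DomainError(f"n outside support [1, {sv.n_max}]")
    if np.any(e_arr < 1) or np.any(e_arr > sv.E):
        raise DomainError(f"eps outside support [1, {sv.E}]")
    out = np.exp(-sol.lambda1 * n_arr - sol.lambda2 * n_arr * e_arr - sol.log_Z)
    return out if out.ndim else float(out)


def abundance_pmf(sol: LagrangeSolution, sv: StateVariables) -> np.ndarray:
    """Marginal P(n) over n = 1..n_max (the species-abundance marginal of R)."""
    n = np.arange(1, sv.n_max + 1, dtype=float)
    logs = -sol.lambda1 * n + _log_eps_integral(sol.lambda2 * n, 0.0, sv.E)
    logs -= special.logsumexp(logs)
    p = np.exp(logs)
    return p / p.sum()


def sample_conditional_eps(n, sol: LagrangeSolution, sv: StateVariables,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw eps | n: truncated exponential, rate ``lambda2 * n``, on [1, E].

    Inverse-CDF sampling; one draw per entry of ``n``.
    """
    n_arr = np.atleast_1d(np.asarray(n, dtype=float))
    a = sol.lambda2 * n_arr
    u = rng.random(n_arr.shape)
    # CDF(eps) = (1 - exp(-a (eps-1))) / (1 - exp(-a (E-1)))
    mass = -np.expm1(-a * (sv.E - 1.0))
    return 1.0 + (-np.log1p(-u * mass)) / a


def sample_structure_function(sol: LagrangeSolution, sv: StateVariables,
                              size: int, rng: np.random.Generator
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Joint draws (n, eps) from R: discrete marginal then conditional."""
    p = abundance_pmf(sol, sv)
    n = rng.choice(np.arange(1, sv.n_max + 1), size=size, p=p)
    eps = sample_conditional_eps(n, sol, sv, rng)
    return n, eps
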