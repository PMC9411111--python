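"""Biomass and productivity predictors: the ecological equation of state.

Given a community's state variables (S, N, E), total biomass follows from the
structure function R and the metabolic-scaling rule ``eps ~ m^theta``:

    B = S * sum_n n * int_1^E eps^(1/theta) R(n, eps | S, N, E) d eps

With the canonical Kleiber exponent theta = 3/4 the integrand power is 4/3 and,
in the regime E >> N >> S >> 1, the sum-integral collapses to the closed form

    B = c * E^(4/3) / (S^(1/3) * ln(1/beta)),     c = (7/2) Gamma(7/3) ≈ 4.17

with beta solved from ``beta ln(1/beta) = S/N``.  Multiplying by the factor
``1 - 1.16 beta^(1/3)`` extends 10%-level accuracy down to N/S ≳ 3, E/N ≳ 5.
Inverting the closed form expresses gross productivity E in terms of S and B,
predicting the S^(1/4) diversity-productivity scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn

from .mete_core import (
    DomainError,
    LagrangeSolution,
    StateVariables,
    joint_moment,
    solve_beta_approx,
    solve_lagrange,
)

__all__ = [
    "BIOMASS_CONSTANT",
    "CORRECTION_COEFFICIENT",
    "ScalingConvention",
    "KLEIBER",
    "SURFACE",
    "ISOMETRIC",
    "RegimeFlags",
    "regime_flags",
    "PredictionResult",
    "predict",
    "predict_biomass_numerical",
    "predict_biomass_analytic",
    "predict_biomass_corrected",
    "correction_factor",
    "predict_productivity",
    "predicted_ratio_curves",
]

#: c = (7/2) * Gamma(7/3), the universal constant of the closed-form state equation.
BIOMASS_CONSTANT = 3.5 * float(_gamma_fn(7.0 / 3.0))

#: coefficient of the finite-beta correction factor 1 - 1.16 * beta**(1/3)
CORRECTION_COEFFICIENT = 1.16

_ALLOWED_EXPONENTS = (0.75, 2.0 / 3.0, 1.0)

# soft thresholds beyond which the closed forms are 10%-accurate
_STRICT_NS, _STRICT_EN = 100.0, 25.0
_RELAXED_NS, _RELAXED_EN = 3.0, 5.0


@dataclass(frozen=True)
class ScalingConvention:
    """Mass-metabolism scaling ``eps ~ m^theta``; theta in {3/4, 2/3, 1}.

    ``biomass_power`` is the reciprocal exponent applied to eps when summing
    or integrating for biomass (4/3, 3/2 or 1).
    """

    metabolic_exponent: float = 0.75

    def __post_init__(self):
        if not any(math.isclose(self.metabolic_exponent, t, rel_tol=1e-12)
                   for t in _ALLOWED_EXPONENTS):
            raise DomainError(
                f"metabolic_exponent must be one of 3/4, 2/3, 1; "
                f"got {self.metabolic_exponent}")

    @property
    def biomass_power(self) -> float:
        return 1.0 / self.metabolic_exponent

    @property
    def is_kleiber(self) -> bool:
        return math.isclose(self.metabolic_exponent, 0.75, rel_tol=1e-12)


KLEIBER = ScalingConvention(0.75)
SURFACE = ScalingConvention(2.0 / 3.0)
ISOMETRIC = ScalingConvention(1.0)


@dataclass(frozen=True)
class RegimeFlags:
    """Soft indicators of the closed forms' stated accuracy regimes."""

    strict: bool   # N/S >= ~100 and E/N >= ~25: plain closed form ~10% accurate
    relaxed: bool  # N/S >= ~3  and E/N >= ~5:  corrected form ~10% accurate


def regime_flags(sv: StateVariables) -> RegimeFlags:
    ns, en = sv.N / sv.S, sv.E / sv.N
    return RegimeFlags(strict=(ns >= _STRICT_NS and en >= _STRICT_EN),
                       relaxed=(ns >= _RELAXED_NS and en >= _RELAXED_EN))


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

def predict_biomass_numerical(sv: StateVariables,
                              convention: ScalingConvention = KLEIBER,
                              tol: float = 1e-10,
                              solution: LagrangeSolution | None = None) -> float:
    """Exact numerical biomass: ``S * <n eps^(1/theta)>`` under the solved R.

    With ``metabolic_exponent = 1`` the moment reduces to the energy
    constraint itself, so the prediction returns E identically.
    """
    sol = solution if solution is not None else solve_lagrange(sv, tol)
    return sv.S * joint_moment(sol, sv, n_power=1.0,
                               eps_power=convention.biomass_power)


def predict_biomass_analytic(sv: StateVariables) -> float:
    """Closed form ``c E^{4/3} / (S^{1/3} ln(1/beta))`` (Kleiber scaling only)."""
    beta = solve_beta_approx(sv)
    return BIOMASS_CONSTANT * sv.E ** (4.0 / 3.0) / (
        sv.S ** (1.0 / 3.0) * math.log(1.0 / beta))


def correction_factor(beta: float) -> float:
    """Finite-beta correction ``1 - 1.16 beta^(1/3)`` to the closed form."""
    return 1.0 - CORRECTION_COEFFICIENT * beta ** (1.0 / 3.0)


def predict_biomass_corrected(sv: StateVariables) -> float:
    """Closed form times the finite-beta correction factor."""
    beta = solve_beta_approx(sv)
    f = correction_factor(beta)
    if f <= 0.0:
        raise DomainError(
            f"correction factor 1 - 1.16*beta^(1/3) = {f:.4f} <= 0 at "
            f"beta={beta:.4f} (N/S={sv.N / sv.S:.2f}); community is far "
            "outside the corrected form's regime")
    return predict_biomass_analytic(sv) * f


def predict_productivity(S: float, B: float, beta: float) -> float:
    """Gross productivity from richness and biomass:
    ``E = c^(-3/4) S^(1/4) B^(3/4) ln^(3/4)(1/beta)`` — the algebraic inverse
    of the closed-form biomass prediction."""
    if S < 2:
        raise DomainError(f"require S >= 2, got {S}")
    if B <= 0:
        raise DomainError(f"require B > 0, got {B}")
    if not 0.0 < beta < 1.0 / math.e:
        raise DomainError(f"require 0 < beta < 1/e, got {beta}")
    return (BIOMASS_CONSTANT ** -0.75 * S ** 0.25 * B ** 0.75
            * math.log(1.0 / beta) ** 0.75)


@dataclass(frozen=True)
class PredictionResult:
    """All predictors evaluated at one state-variable triple."""

    sv: StateVariables
    convention: ScalingConvention
    solution: LagrangeSolution
    B_numerical: float
    B_analytic: float | None
    B_corrected: float | None
    ratio_pred: float  # E / B_numerical ** metabolic_exponent
    flags: RegimeFlags

    def to_record(self) -> dict:
        rec = {"S": self.sv.S, "N": self.sv.N, "E": self.sv.E,
               "metabolic_exponent": self.convention.metabolic_exponent}
        rec.update(self.solution.to_record())
        rec.update({"B_numerical": self.B_numerical,
                    "B_analytic": self.B_analytic,
                    "B_corrected": self.B_corrected,
                    "ratio_pred": self.ratio_pred,
                    "regime_strict": self.flags.strict,
                    "regime_relaxed": self.flags.relaxed})
        return rec


def predict(sv: StateVariables, convention: ScalingConvention = KLEIBER,
            tol: float = 1e-10) -> PredictionResult:
    """Bundle the numerical predictor with the closed forms (where defined).

    The closed forms exist only for Kleiber scaling; under other exponents
    they are reported as ``None``.  The corrected form is ``None`` when its
    correction factor is non-positive (community far below N/S ~ 3).
    """
    sol = solve_lagrange(sv, tol)
    b_num = predict_biomass_numerical(sv, convention, tol, solution=sol)
    b_ana = b_cor = None
    if convention.is_kleiber:
        b_ana = predict_biomass_analytic(sv)
        try:
            b_cor = predict_biomass_corrected(sv)
        except DomainError:
            b_cor = None
    ratio = sv.E / b_num ** convention.metabolic_exponent
    return PredictionResult(sv=sv, convention=convention, solution=sol,
                            B_numerical=b_num, B_analytic=b_ana,
                            B_corrected=b_cor, ratio_pred=ratio,
                            flags=regime_flags(sv))


def predicted_ratio_curves(varying: str, values, *, S: float | None = None,
                           N: float | None = None, E: float | None = None,
                           convention: ScalingConvention = KLEIBER,
                           tol: float = 1e-10) -> pd.DataFrame:
    """Predicted ``E / B^theta`` along a grid in one state variable.

    Exactly one of S, N varies (``varying`` in {"S", "N"}); E and the other
    variable are held fixed.  Grid points that violate the state-variable
    ordering S < N < E are skipped with a warning.
    """
    if varying not in ("S", "N"):
        raise DomainError(f"varying must be 'S' or 'N', got {varying!r}")
    fixed = {"S": S, "N": N, "E": E}
    if fixed[varying] is not None:
        raise DomainError(f"{varying} is the varying axis; do not fix it")
    missing = [k for k, v in fixed.items() if v is None and k != varying]
    if missing:
        raise DomainError(f"fixed values required for {missing}")

    rows = []
    for v in np.asarray(values, dtype=float):
        kw = dict(fixed)
        kw[varying] = float(v)
        try:
            sv = StateVariables(**kw)
            b = predict_biomass_numerical(sv, convention, tol)
        except DomainError as exc:
            warnings.warn(f"skipping {varying}={v}: {exc}", stacklevel=2)
            continue
        rows.append({varying: float(v), "S": sv.S, "N": sv.N, "E": sv.E,
                     "B_numerical": b,
                     "ratio": sv.E / b ** convention.metabolic_exponent})
    return pd.DataFrame(rows)
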