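"""Observed-vs-predicted comparisons and variance-explained summaries.

Given a collection of plots with observed (S, N, E, B), each plot's biomass is
predicted numerically from its own observed (S, N, E) and compared to the
observed B on log scale, along with the ratio ``E / B^theta``.  "Variance
explained" is reported two ways, because the phrase is ambiguous in common
usage: the squared correlation between the two quantities (regression R^2),
and the coefficient of determination about the identity line y = x (which can
be negative and is reported as-is).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census_processing import ObservedStateVariables, observed_ratio
from .equation_of_state import KLEIBER, PredictionResult, ScalingConvention, predict
from .mete_core import DomainError, SolverError

__all__ = [
    "PlotComparison",
    "VarianceExplainedReport",
    "compare_plots",
    "comparison_table",
    "variance_explained",
    "pairwise_scatter_table",
    "plot_observed_vs_predicted",
]

logger = logging.getLogger(__name__)

_QUANTITIES = ("lnB", "ratio")


@dataclass(frozen=True)
class PlotComparison:
    """One plot's observed quantities next to its predictions."""

    plot_label: str
    observed: ObservedStateVariables
    predicted: PredictionResult
    ln_B_obs: float
    ln_B_pred: float
    ratio_obs: float
    ratio_pred: float


@dataclass(frozen=True)
class VarianceExplainedReport:
    """Two readings of 'variance explained' for one quantity."""

    quantity: str
    n_plots: int
    r2_regression: float  # squared Pearson correlation
    r2_identity: float    # 1 - SS_about_identity / SS_total; may be negative
    degenerate: bool = False


def compare_plots(observations, convention: ScalingConvention = KLEIBER,
                  tol: float = 1e-10) -> list[PlotComparison]:
    """Predict each plot's biomass from its observed (S, N, E).

    Plots whose solve fails are excluded with a logged reason, never silently.
    """
    out = []
    for obs in observations:
        try:
            pred = predict(obs.state_variables, convention, tol)
        except (DomainError, SolverError) as exc:
            logger.warning("excluding plot %r: %s", obs.plot_label, exc)
            continue
        out.append(PlotComparison(
            plot_label=obs.plot_label, observed=obs, predicted=pred,
            ln_B_obs=math.log(obs.B), ln_B_pred=math.log(pred.B_numerical),
            ratio_obs=observed_ratio(obs), ratio_pred=pred.ratio_pred))
    return out


def comparison_table(comparisons) -> pd.DataFrame:
    """Flat table of the comparisons (one row per plot)."""
    return pd.DataFrame([{
        "plot_label": c.plot_label,
        "S": c.observed.S, "N": c.observed.N, "E": c.observed.E,
        "B_observed": c.observed.B, "B_predicted": c.predicted.B_numerical,
        "ln_B_obs": c.ln_B_obs, "ln_B_pred": c.ln_B_pred,
        "ratio_obs": c.ratio_obs, "ratio_pred": c.ratio_pred,
    } for c in comparisons])


def _r2_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """(regression R^2, identity-line R^2, degenerate flag)."""
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0 or float(np.ptp(x)) == 0.0:
        return math.nan, math.nan, True
    r = float(np.corrcoef(x, y)[0, 1])
    r2_identity = 1.0 - float(np.sum((y - x) ** 2)) / ss_tot
    return r * r, r2_identity, False


def variance_explained(comparisons, quantity: str = "lnB"
                       ) -> VarianceExplainedReport:
    """Variance in the observed quantity explained by the predicted one.

    ``quantity``: "lnB" (log biomass) or "ratio" (raw E / B^theta).
    Requires at least 3 plots.
    """
    if quantity not in _QUANTITIES:
        raise DomainError(f"quantity must be one of {_QUANTITIES}, got {quantity!r}")
    comps = list(comparisons)
    if len(comps) < 3:
        raise DomainError(f"need >= 3 plots for variance explained, got {len(comps)}")
    if quantity == "lnB":
        x = np.array([c.ln_B_pred for c in comps])
        y = np.array([c.ln_B_obs for c in comps])
    else:
        x = np.array([c.ratio_pred for c in comps])
        y = np.array([c.ratio_obs for c in comps])
    r2_reg, r2_id, degenerate = _r2_pair(x, y)
    return VarianceExplainedReport(quantity=quantity, n_plots=len(comps),
                                   r2_regression=r2_reg, r2_identity=r2_id,
                                   degenerate=degenerate)


def pairwise_scatter_table(observations) -> pd.DataFrame:
    """Regression R^2 for all 6 unordered pairs among lnS, lnN, lnE, lnB.

    On field data these pairwise relationships are typically weak — the point
    of the full equation of state is that no pair predicts a third variable
    well on its own.  Degenerate pairs (zero variance) carry NaN and a flag.
    """
    obs = list(observations)
    if len(obs) < 3:
        raise DomainError(f"need >= 3 plots, got {len(obs)}")
    cols = {
        "lnS": np.log([o.S for o in obs]),
        "lnN": np.log([o.N for o in obs]),
        "lnE": np.log([o.E for o in obs]),
        "lnB": np.log([o.B for o in obs]),
    }
    rows = []
    for (nx, x), (ny, y) in itertools.combinations(cols.items(), 2):
        r2, _, degenerate = _r2_pair(np.asarray(x), np.asarray(y))
        rows.append({"x": nx, "y": ny, "r2_regression": r2,
                     "degenerate": degenerate, "n_plots": len(obs)})
    return pd.DataFrame(rows)


def plot_observed_vs_predicted(comparisons, quantity: str = "lnB", path=None):
    """Observed-vs-predicted scatter with the identity line (optional output).

    Imports matplotlib lazily; install the ``plots`` extra to use this.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = list(comparisons)
    if quantity == "lnB":
        x = [c.ln_B_pred for c in comps]
        y = [c.ln_B_obs for c in comps]
        labels = ("ln(predicted biomass)", "ln(observed biomass)")
    else:
        x = [c.ratio_pred for c in comps]
        y = [c.ratio_obs for c in comps]
        labels = ("predicted E / B^theta", "observed E / B^theta")
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=18, alpha=0.8)
    lo, hi = min(min(x), min(y)), max(max(x), max(y))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="identity")
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
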