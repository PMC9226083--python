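"""Derived demographic outputs: longevity-class expectations, survival curves,
crude annual survival, and time to near-maximal annual survival.

Fitted annual-survival functions are evaluated beyond the observation window
to draw extrapolated survival curves (the default horizon is 10 years);
extrapolated years are flagged so downstream tables and plots can mark them —
projections past the window ignore episodic disturbance and deserve caution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import SurvivorshipResults
from .models import (
    LogisticSurvival,
    LongevityDistribution,
    SurvivalModel,
    longevity_distribution,
)

__all__ = [
    "SurvivalCurve",
    "expected_longevity_classes",
    "crude_constant_survival",
    "survival_curve",
    "survival_curves",
    "years_to_fraction_of_max",
    "plot_longevity_classes",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Annual and cumulative survival on an integer-year grid.

    ``annual[t]`` is ``s_t`` (with ``s_0 = 1``); ``cumulative[t]`` is
    ``prod_{i<=t} s_i``, the probability of being alive at year ``t``.
    ``extrapolated[t]`` is True past the fitted observation window.
    """

    years: np.ndarray
    annual: np.ndarray
    cumulative: np.ndarray
    extrapolated: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative) > 1e-12):
            raise ValueError("cumulative survival must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "annual_survival": self.annual,
                "cumulative_survival": self.cumulative,
                "extrapolated": self.extrapolated,
            }
        )


def survival_curve(
    model: SurvivalModel, horizon: int = 10, window_years: int = 4, label: str = ""
) -> SurvivalCurve:
    """Evaluate a fitted survival function out to ``horizon`` years.

    Years beyond ``window_years`` re-evaluate the fitted function (rather
    than holding the last within-window rate fixed) and are flagged as
    extrapolation.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    annual = model.annual_survival_path(horizon)
    years = np.arange(horizon + 1)
    return SurvivalCurve(
        years=years,
        annual=annual,
        cumulative=np.cumprod(annual),
        extrapolated=years > window_years,
        label=label,
    )


def survival_curves(fit: SurvivorshipResults, horizon: int = 10) -> dict[str, SurvivalCurve]:
    """Per-stratum survival curves from a converged fit."""
    if not fit.converged:
        raise ValueError("survival curves require a converged fit")
    T = fit.window_years
    return {
        stratum: survival_curve(m, horizon=horizon, window_years=T, label=f"{fit.grouping}/{stratum}")
        for stratum, m in fit.stratum_models.items()
    }


def expected_longevity_classes(
    fit: SurvivorshipResults, window_years: int | None = None
) -> LongevityDistribution:
    """Expected share of the cohort in each longevity class under a fit.

    For two-habitat structures the per-stratum distributions are mixed with
    weights equal to the stratum sample shares, matching how the pooled
    empirical bars are composed.
    """
    if not fit.converged:
        raise ValueError("longevity expectations require a converged fit")
    return fit.longevity_distribution(window_years=window_years)


def crude_constant_survival(p_survive_window: float, window_years: int) -> float:
    """Constant annual survival implied by a whole-window survival share.

    If a fraction ``p`` of the cohort survives ``T`` years and survival is
    assumed constant, the annual rate is ``p ** (1/T)``.
    """
    if not 0.0 < p_survive_window <= 1.0:
        raise ValueError(f"p_survive_window must lie in (0, 1], got {p_survive_window}")
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    return float(p_survive_window ** (1.0 / window_years))


def years_to_fraction_of_max(model: LogisticSurvival, fraction: float = 0.99) -> int:
    """Smallest integer year at which annual survival reaches ``fraction`` of
    its asymptote.

    For the logistic family ``s_t / s = 1 / (1 + e^{-bt})``, so the threshold
    is ``ceil(ln(fraction / (1 - fraction)) / b)`` (never less than year 1).
    Requires ``b > 0``: with declining survival the asymptote is approached
    from above at t=0 and the question is vacuous.
    """
    if not isinstance(model, LogisticSurvival):
        raise TypeError("years_to_fraction_of_max applies to logistic survival models")
    if model.b <= 0:
        raise ValueError("b must be positive to approach the asymptote from below")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    # epsilon guards float ties at exact-integer thresholds
    t = math.ceil(math.log(fraction / (1.0 - fraction)) / model.b - 1e-12)
    return max(1, t)


def plot_longevity_classes(
    fit: SurvivorshipResults,
    empirical: np.ndarray | None = None,
    ax=None,
):
    """Bar-plus-line longevity plot: empirical class shares as bars, the
    fitted expectation as a line. Returns the matplotlib axes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    dist = expected_longevity_classes(fit)
    x = np.arange(len(dist.probs))
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if empirical is not None:
        ax.bar(x, np.asarray(empirical, dtype=float), color="0.8", label="observed")
    ax.plot(x, dist.probs, marker="o", color="C0", label=f"model {fit.structure.id}")
    ax.set_xticks(x)
    ax.set_xticklabels(dist.labels)
    ax.set_xlabel("longevity class (years)")
    ax.set_ylabel("proportion of cohort")
    ax.set_title(fit.grouping)
    ax.legend(frameon=False)
    return ax
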