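"""Annual-survival models and the censored longevity likelihood they induce.

A cohort of colonies is detected at an initial survey (year 0) and revisited
annually. Survivorship is described in discrete time by ``s_t``, the
probability of surviving the interval from year ``t-1`` to year ``t``. By
construction ``s_0 = 1``: a colony had to survive to year 0 to be detected at
all. Two parametric families are supported:

* constant survival, ``s_t = s_c`` for every ``t >= 1`` (age-independent); and
* logistic survival, ``s_t = s / (1 + exp(-b t))``, which rises with age
  toward the asymptote ``s`` when ``b > 0``.

A colony's *longevity* is the truncated integer number of annual intervals it
survived after detection. Observed over a window of ``T`` years, longevity
``t < T`` occurs with probability ``(1 - s_{t+1}) * prod_{i=0..t} s_i``;
colonies alive at the final survey are right-censored into the terminal
``>= T`` class, with probability ``prod_{i=0..T} s_i``. These class
probabilities sum to one by telescoping, so a cohort of independent colonies
is multinomial over the ``T + 1`` longevity classes and the cohort
log-likelihood is the sum of log class probabilities over colonies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

__all__ = [
    "ConstantSurvival",
    "LogisticSurvival",
    "SurvivalModel",
    "LongevityDistribution",
    "longevity_distribution",
    "log_likelihood",
    "observations_to_counts",
    "model_from_dict",
]


@dataclass(frozen=True)
class ConstantSurvival:
    """Age-independent annual survival: ``s_t = s_c`` for every ``t >= 1``.

    Parameters
    ----------
    s_c : float
        Annual survival probability, in ``(0, 1]``.
    """

    s_c: float

    family = "constant"
    n_params = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.s_c <= 1.0:
            raise ValueError(f"s_c must lie in (0, 1], got {self.s_c}")

    def annual_survival(self, t: int) -> float:
        """Survival probability for the interval ``(t-1, t]``; 1 at ``t = 0``."""
        if t < 0:
            raise ValueError(f"t must be a non-negative integer, got {t}")
        return 1.0 if t == 0 else self.s_c

    def annual_survival_path(self, horizon: int) -> np.ndarray:
        """Vector ``[s_0, s_1, ..., s_horizon]``."""
        out = np.full(horizon + 1, self.s_c)
        out[0] = 1.0
        return out

    @property
    def params(self) -> dict:
        return {"s_c": self.s_c}

    def to_dict(self) -> dict:
        return {"family": self.family, "params": {"s_c": float(self.s_c)}}


@dataclass(frozen=True)
class LogisticSurvival:
    """Age-dependent annual survival ``s_t = s / (1 + exp(-b t))`` for ``t >= 1``.

    With ``b > 0`` survival rises from ``s_1 = s / (1 + e^{-b})`` toward the
    asymptote ``s``; ``b < 0`` (declining survival with age) is permitted.
    ``s_0 = 1`` by the detection conditioning.

    Parameters
    ----------
    s : float
        Asymptotic annual survival, in ``(0, 1]``.
    b : float
        Rate of approach to the asymptote, per year; any finite real.
    """

    s: float
    b: float

    family = "logistic"
    n_params = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.s <= 1.0:
            raise ValueError(f"s must lie in (0, 1], got {self.s}")
        if not np.isfinite(self.b):
            raise ValueError(f"b must be finite, got {self.b}")

    def annual_survival(self, t: int) -> float:
        if t < 0:
            raise ValueError(f"t must be a non-negative integer, got {t}")
        if t == 0:
            return 1.0
        return self.s / (1.0 + np.exp(-self.b * t))

    def annual_survival_path(self, horizon: int) -> np.ndarray:
        t = np.arange(horizon + 1, dtype=float)
        with np.errstate(over="ignore"):
            out = self.s / (1.0 + np.exp(-self.b * t))
        out[0] = 1.0
        return out

    @property
    def params(self) -> dict:
        return {"s": self.s, "b": self.b}

    def to_dict(self) -> dict:
        return {"family": self.family, "params": {"s": float(self.s), "b": float(self.b)}}


SurvivalModel = Union[ConstantSurvival, LogisticSurvival]


def model_from_dict(d: dict) -> SurvivalModel:
    """Rebuild a survival model from its ``{"family", "params"}`` dict form."""
    family = d["family"]
    if family == "constant":
        return ConstantSurvival(**d["params"])
    if family == "logistic":
        return LogisticSurvival(**d["params"])
    raise ValueError(f"unknown survival family {family!r}")


@dataclass(frozen=True)
class LongevityDistribution:
    """Probabilities over the longevity classes ``0, 1, ..., T-1, >=T``.

    ``probs[t]`` for ``t < T`` is the probability of surviving exactly ``t``
    full annual intervals; ``probs[T]`` is the right-censored class of
    colonies alive at the final survey.
    """

    window_years: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.shape != (self.window_years + 1,):
            raise ValueError(
                f"expected {self.window_years + 1} class probabilities, got {probs.shape}"
            )
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise ValueError("longevity class probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"longevity class probabilities sum to {probs.sum()}, not 1")

    @property
    def labels(self) -> list[str]:
        return [str(t) for t in range(self.window_years)] + [f">={self.window_years}"]

    def __getitem__(self, t: int) -> float:
        return float(self.probs[t])

    @property
    def censored_prob(self) -> float:
        """Probability of surviving the whole window (the ``>=T`` class)."""
        return float(self.probs[-1])


def longevity_distribution(model: SurvivalModel, window_years: int) -> LongevityDistribution:
    """Longevity-class distribution induced by a survival model over ``T`` years.

    ``P(longevity = t) = (1 - s_{t+1}) * prod_{i=0..t} s_i`` for ``t < T`` and
    ``P(longevity >= T) = prod_{i=0..T} s_i``. Accumulated in log space so long
    windows do not underflow.
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    s = model.annual_survival_path(window_years)
    with np.errstate(divide="ignore"):
        log_cum = np.cumsum(np.log(s))  # log prod_{i=0..t} s_i
    probs = np.empty(window_years + 1)
    # death in (t, t+1]: survived intervals 1..t then failed interval t+1
    probs[:-1] = np.exp(log_cum[:-1]) * (1.0 - s[1:])
    probs[-1] = np.exp(log_cum[-1])
    return LongevityDistribution(window_years, probs)


def observations_to_counts(observations: Iterable, window_years: int) -> np.ndarray:
    """Tally longevity observations into per-class counts.

    Accepts objects with ``longevity`` and ``censored`` attributes (e.g.
    :class:`coralrec.cohort.LongevityObservation`) or ``(longevity, censored)``
    pairs. Returns an integer vector of length ``T + 1`` whose last entry
    counts the censored ``>=T`` class.
    """
    counts = np.zeros(window_years + 1, dtype=np.int64)
    for obs in observations:
        if hasattr(obs, "longevity"):
            t, censored = obs.longevity, obs.censored
        else:
            t, censored = obs
        if t < 0 or t > window_years:
            raise ValueError(
                f"longevity {t} outside the 0..{window_years} observation window"
            )
        if censored:
            if t != window_years:
                raise ValueError(
                    f"censored observation must have longevity {window_years}, got {t}"
                )
            counts[window_years] += 1
        else:
            if t == window_years:
                raise ValueError(
                    f"uncensored longevity {t} is impossible over a {window_years}-year window"
                )
            counts[t] += 1
    return counts


def log_likelihood(model: SurvivalModel, observations: Iterable, window_years: int) -> float:
    """Cohort log-likelihood: sum of log longevity-class probabilities.

    Colony fates are assumed independent (binomial error structure), so the
    cohort is multinomial over longevity classes and the log-likelihood is
    ``sum_class count_class * ln(P_class)``. Returns ``-inf`` if any observed
    class has probability zero under the model.
    """
    counts = observations_to_counts(observations, window_years)
    return counts_log_likelihood(model, counts, window_years)


def counts_log_likelihood(model: SurvivalModel, counts: np.ndarray, window_years: int) -> float:
    """Log-likelihood from pre-tallied longevity-class counts."""
    probs = longevity_distribution(model, window_years).probs
    observed = counts > 0
    if np.any(probs[observed] <= 0.0):
        return -np.inf
    return float(np.dot(counts[observed], np.log(probs[observed])))
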