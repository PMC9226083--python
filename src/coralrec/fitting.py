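"""Maximum-likelihood fitting of the six candidate survivorship structures.

The candidate set crosses two survival families (constant, logistic) with two
habitat treatments (pooled, or independent parameters per substrate class):

====  =================================================  ========
 id    structure                                          params
====  =================================================  ========
 1     one habitat, constant                               1
 2     one habitat, logistic                               2
 3     constant (unconsolidated) + constant (consolid.)    2
 4     constant (unconsolidated) + logistic (consolid.)    3
 5     logistic (unconsolidated) + constant (consolid.)    3
 6     logistic (unconsolidated) + logistic (consolid.)    4
====  =================================================  ========

Two-habitat structures share no parameters across strata, so their
log-likelihoods add. Fitting follows the statsmodels idiom: build a
:class:`SurvivorshipMLE` model from longevity observations, call
:meth:`SurvivorshipMLE.fit`, and work with the returned
:class:`SurvivorshipResults`.

Optimisation is Nelder-Mead on an unconstrained internal parameterisation
(logit transform for survival probabilities, identity for the logistic rate
``b``), with multi-start restarts jittered around moment-based initial values
(the crude annual survival implied by person-year exposure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .cohort import CohortTable, LongevityObservation, derive_longevities, stratify
from .models import (
    ConstantSurvival,
    LogisticSurvival,
    LongevityDistribution,
    SurvivalModel,
    counts_log_likelihood,
    observations_to_counts,
)

__all__ = [
    "ModelStructure",
    "MODEL_STRUCTURES",
    "SurvivorshipMLE",
    "SurvivorshipResults",
    "FitGrid",
    "fit_structure",
    "fit_all",
]

POOLED_LABEL = "all"
STRATA_ORDER = ("unconsolidated", "consolidated")  # column-order convention
BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class ModelStructure:
    """One of the six candidate structures (habitat treatment x family)."""

    id: int
    habitat_split: bool
    family_unconsolidated: str
    family_consolidated: str

    @property
    def families(self) -> tuple[tuple[str, str], ...]:
        """Ordered ``(stratum, family)`` pairs this structure fits."""
        if not self.habitat_split:
            return ((POOLED_LABEL, self.family_consolidated),)
        return (
            ("unconsolidated", self.family_unconsolidated),
            ("consolidated", self.family_consolidated),
        )

    @property
    def n_params(self) -> int:
        per = {"constant": 1, "logistic": 2}
        return sum(per[f] for _, f in self.families)

    @property
    def label(self) -> str:
        if not self.habitat_split:
            return self.family_consolidated.capitalize()
        return (
            f"{self.family_unconsolidated.capitalize()} + {self.family_consolidated}"
        )


MODEL_STRUCTURES: dict[int, ModelStructure] = {
    1: ModelStructure(1, False, "constant", "constant"),
    2: ModelStructure(2, False, "logistic", "logistic"),
    3: ModelStructure(3, True, "constant", "constant"),
    4: ModelStructure(4, True, "constant", "logistic"),
    5: ModelStructure(5, True, "logistic", "constant"),
    6: ModelStructure(6, True, "logistic", "logistic"),
}


def _as_structure(structure) -> ModelStructure:
    if isinstance(structure, ModelStructure):
        return structure
    return MODEL_STRUCTURES[int(structure)]


def _build_model(family: str, theta: np.ndarray) -> SurvivalModel:
    if family == "constant":
        return ConstantSurvival(s_c=float(expit(theta[0])))
    return LogisticSurvival(s=float(expit(theta[0])), b=float(theta[1]))


class SurvivorshipMLE:
    """Maximum-likelihood model for censored longevity observations.

    Parameters
    ----------
    observations : iterable of LongevityObservation
        One entry per colony; ``habitat`` is consulted only when the
        structure splits by habitat.
    structure : int or ModelStructure
        Candidate structure id 1-6 (see module docstring).
    window_years : int
        Observation window ``T``; censoring occurs at the ``>=T`` class.
    grouping : str
        Label carried through to results tables ("All corals" or a taxon).
    """

    def __init__(
        self,
        observations: Iterable[LongevityObservation],
        structure=1,
        window_years: int = 4,
        grouping: str = "All corals",
    ):
        self.structure = _as_structure(structure)
        self.window_years = int(window_years)
        self.grouping = grouping
        observations = list(observations)
        if not observations:
            raise ValueError("no observations to fit")
        self.nobs = len(observations)

        # multinomial sufficient statistics: per-stratum longevity-class counts
        self._counts: dict[str, np.ndarray] = {}
        if self.structure.habitat_split:
            for stratum, _ in self.structure.families:
                obs_s = [o for o in observations if o.habitat == stratum]
                if not obs_s:
                    raise ValueError(
                        f"habitat stratum {stratum!r} has no observations; "
                        "a two-habitat structure cannot be fit"
                    )
                self._counts[stratum] = observations_to_counts(obs_s, self.window_years)
        else:
            self._counts[POOLED_LABEL] = observations_to_counts(
                observations, self.window_years
            )

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, structure=1, window_years: int = 4, grouping: str = "All corals"
    ) -> "SurvivorshipMLE":
        """Build from a longevity-wide frame (columns longevity, censored, habitat)."""
        obs = [
            LongevityObservation(
                longevity=int(row.longevity),
                censored=bool(row.censored),
                taxon=str(getattr(row, "taxon", "")),
                habitat=str(row.habitat),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(obs, structure=structure, window_years=window_years, grouping=grouping)

    @classmethod
    def from_cohort(
        cls, cohort: CohortTable, structure=1, taxon: str | None = None
    ) -> "SurvivorshipMLE":
        """Build from a fate table, optionally restricted to one taxon."""
        sub = cohort if taxon is None else cohort.subset(taxon=taxon)
        return cls(
            derive_longevities(sub),
            structure=structure,
            window_years=cohort.window_years,
            grouping=taxon or "All corals",
        )

    # -- likelihood ---------------------------------------------------------

    def _split_theta(self, theta: np.ndarray) -> dict[str, SurvivalModel]:
        models = {}
        i = 0
        for stratum, family in self.structure.families:
            k = 1 if family == "constant" else 2
            models[stratum] = _build_model(family, theta[i : i + k])
            i += k
        return models

    def loglike(self, theta: np.ndarray) -> float:
        """Log-likelihood at an internal (unconstrained) parameter vector."""
        total = 0.0
        for stratum, model in self._split_theta(np.asarray(theta, dtype=float)).items():
            total += counts_log_likelihood(model, self._counts[stratum], self.window_years)
        return total

    def loglike_models(self, models: Mapping[str, SurvivalModel]) -> float:
        """Log-likelihood at natural-scale survival models, one per stratum."""
        return sum(
            counts_log_likelihood(models[stratum], counts, self.window_years)
            for stratum, counts in self._counts.items()
        )

    # -- initial values -----------------------------------------------------

    def _crude_annual_survival(self, stratum: str) -> float:
        """Person-year estimate: intervals survived / intervals at risk."""
        counts = self._counts[stratum]
        T = self.window_years
        survived = sum(t * counts[t] for t in range(T)) + T * counts[T]
        deaths = int(counts[:T].sum())
        at_risk = survived + deaths
        if at_risk == 0:
            return 0.5
        return float(np.clip(survived / at_risk, 0.02, 0.995))

    def _start_vectors(self) -> list[np.ndarray]:
        """Deterministic starts: moment-based b=1, plus (for logistic
        families) a large-b start from which the near-constant ridge is
        reachable when the data carry no age signal."""
        base, high_b = [], []
        any_logistic = False
        for stratum, family in self.structure.families:
            s0 = self._crude_annual_survival(stratum)
            base.append(logit(s0))
            high_b.append(logit(s0))
            if family == "logistic":
                any_logistic = True
                base.append(1.0)
                high_b.append(8.0)
        starts = [np.array(base, dtype=float)]
        if any_logistic:
            starts.append(np.array(high_b, dtype=float))
        return starts

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        seed: int | None = None,
        n_restarts: int = 8,
        maxiter: int = 2000,
        fatol: float = 1e-8,
        xatol: float = 1e-6,
    ) -> "SurvivorshipResults":
        """Maximise the likelihood by multi-start Nelder-Mead.

        The first start is the moment-based vector; the rest are jittered
        around it with a generator seeded by ``seed``, so fits are
        reproducible. Returns the best restart as a
        :class:`SurvivorshipResults`.
        """
        rng = np.random.default_rng(seed)
        deterministic = self._start_vectors()
        base = deterministic[0]

        def objective(theta):
            ll = self.loglike(theta)
            return 1e12 if not np.isfinite(ll) else -ll

        best = None
        any_success = False
        for r in range(max(1, n_restarts)):
            if r < len(deterministic):
                start = deterministic[r]
            else:
                start = base + rng.normal(0.0, 1.0, size=base.size)
            res = minimize(
                objective,
                start,
                method="Nelder-Mead",
                options={
                    "maxiter": maxiter,
                    "fatol": fatol,
                    "xatol": xatol,
                },
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res

        theta_hat = np.asarray(best.x, dtype=float)
        models = self._split_theta(theta_hat)
        llf = self.loglike(theta_hat)

        params: dict[str, float] = {}
        at_boundary: list[str] = []
        single = not self.structure.habitat_split
        for stratum, model in models.items():
            prefix = "" if single else f"{stratum}."
            for name, value in model.params.items():
                params[f"{prefix}{name}"] = value
                if name in ("s", "s_c") and value > 1.0 - BOUNDARY_TOL:
                    at_boundary.append(f"{prefix}{name}")

        total = sum(c.sum() for c in self._counts.values())
        weights = {s: float(c.sum() / total) for s, c in self._counts.items()}
        return SurvivorshipResults(
            structure=self.structure,
            params=params,
            stratum_models=models,
            llf=float(llf),
            converged=bool(any_success and np.isfinite(llf)),
            at_boundary=tuple(at_boundary),
            n_restarts_used=max(1, n_restarts),
            grouping=self.grouping,
            nobs=self.nobs,
            window_years=self.window_years,
            weights=weights,
            model=self,
        )


@dataclass(frozen=True)
class SurvivorshipResults:
    """Fit results: estimates, likelihood, diagnostics, derived quantities."""

    structure: ModelStructure
    params: dict[str, float]
    stratum_models: dict[str, SurvivalModel]
    llf: float
    converged: bool
    at_boundary: tuple[str, ...]
    n_restarts_used: int
    grouping: str
    nobs: int
    window_years: int
    weights: dict[str, float]
    model: SurvivorshipMLE | None = None

    @property
    def n_params(self) -> int:
        return self.structure.n_params

    @property
    def aic(self) -> float:
        """Akaike information criterion, ``-2 ln L + 2 n``."""
        return -2.0 * self.llf + 2.0 * self.n_params

    def stratum_weights(self) -> dict[str, float]:
        """Sample share of each stratum (1.0 for pooled structures)."""
        return dict(self.weights)

    def longevity_distribution(self, window_years: int | None = None) -> LongevityDistribution:
        """Model-expected longevity-class distribution.

        For two-habitat structures this is the mixture of per-stratum
        distributions weighted by stratum sample shares.
        """
        from .models import longevity_distribution as _ld

        T = self.window_years if window_years is None else int(window_years)
        probs = sum(
            self.weights[stratum] * _ld(m, T).probs
            for stratum, m in self.stratum_models.items()
        )
        return LongevityDistribution(T, probs)

    def summary(self) -> str:
        """Human-readable fit summary in the statsmodels style."""
        lines = []
        title = "Juvenile Coral Survivorship MLE"
        lines.append(title.center(58))
        lines.append("=" * 58)
        lines.append(f"{'Grouping:':<16}{self.grouping:<22}{'Model:':<9}{self.structure.id} ({self.structure.label})")
        lines.append(f"{'N colonies:':<16}{self.nobs:<22}{'Window:':<9}{self.window_years} years")
        lines.append(f"{'Log-likelihood:':<16}{self.llf:<22.4f}{'AIC:':<9}{self.aic:.4f}")
        lines.append(f"{'Converged:':<16}{str(self.converged):<22}{'Restarts:':<9}{self.n_restarts_used}")
        lines.append("-" * 58)
        lines.append(f"{'stratum':<16}{'family':<11}{'param':<8}{'estimate':>10}")
        for stratum, m in self.stratum_models.items():
            for name, value in m.params.items():
                lines.append(f"{stratum:<16}{m.family:<11}{name:<8}{value:>10.4f}")
        if self.at_boundary:
            lines.append("-" * 58)
            lines.append(f"Note: estimate(s) at the s=1 boundary: {', '.join(self.at_boundary)}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def to_row(self) -> dict:
        """Flat record for results tables / CSV export."""
        import json

        return {
            "grouping": self.grouping,
            "model_id": self.structure.id,
            "n_params": self.n_params,
            "loglik": self.llf,
            "aic": self.aic,
            "converged": self.converged,
            "nobs": self.nobs,
            "window_years": self.window_years,
            "params": json.dumps(
                {s: m.to_dict() for s, m in self.stratum_models.items()}, sort_keys=True
            ),
            "weights": json.dumps(
                {s: round(w, 12) for s, w in self.stratum_weights().items()}, sort_keys=True
            ),
            "at_boundary": ";".join(self.at_boundary),
        }

    @classmethod
    def from_row(cls, row: Mapping) -> "SurvivorshipResults":
        """Rebuild results from a :meth:`to_row` record (e.g. a CSV row)."""
        import json

        from .models import model_from_dict

        stratum_models = {
            s: model_from_dict(d) for s, d in json.loads(row["params"]).items()
        }
        structure = MODEL_STRUCTURES[int(row["model_id"])]
        params: dict[str, float] = {}
        single = not structure.habitat_split
        for stratum, m in stratum_models.items():
            prefix = "" if single else f"{stratum}."
            for name, value in m.params.items():
                params[f"{prefix}{name}"] = value
        converged = row["converged"]
        if isinstance(converged, str):
            converged = converged.strip().lower() in ("true", "1")
        at_boundary = row.get("at_boundary", "") or ""
        if isinstance(at_boundary, float):  # NaN from pandas
            at_boundary = ""
        return cls(
            structure=structure,
            params=params,
            stratum_models=stratum_models,
            llf=float(row["loglik"]),
            converged=bool(converged),
            at_boundary=tuple(t for t in str(at_boundary).split(";") if t),
            n_restarts_used=0,
            grouping=str(row["grouping"]),
            nobs=int(row["nobs"]),
            window_years=int(row["window_years"]),
            weights=json.loads(row["weights"]),
        )


def fit_structure(
    observations: Sequence[LongevityObservation],
    structure,
    window_years: int = 4,
    seed: int | None = None,
    grouping: str = "All corals",
    **fit_kwargs,
) -> SurvivorshipResults:
    """One-call fit of a single candidate structure to observations."""
    return SurvivorshipMLE(
        observations, structure=structure, window_years=window_years, grouping=grouping
    ).fit(seed=seed, **fit_kwargs)


@dataclass
class FitGrid:
    """Fits over the (grouping x structure) grid, with skipped/failed cells."""

    results: dict[tuple[str, int], SurvivorshipResults] = field(default_factory=dict)
    skipped: list[tuple[str, int, str]] = field(default_factory=list)

    def for_grouping(self, grouping: str) -> list[SurvivorshipResults]:
        return [r for (g, _), r in sorted(self.results.items()) if g == grouping]

    def get(self, grouping: str, model_id: int) -> SurvivorshipResults | None:
        return self.results.get((grouping, model_id))

    @property
    def groupings(self) -> list[str]:
        seen: list[str] = []
        for g, _ in self.results:
            if g not in seen:
                seen.append(g)
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = [r.to_row() for _, r in sorted(self.results.items(), key=lambda kv: (kv[0][0], kv[0][1]))]
        return pd.DataFrame(rows)


def fit_all(
    cohort: CohortTable,
    structures: Sequence[int] = (1, 2, 3, 4, 5, 6),
    min_total: int = 10,
    min_per_habitat: int = 5,
    seed: int | None = None,
    n_restarts: int = 8,
) -> FitGrid:
    """Fit every eligible (grouping, structure) pair over a cohort.

    Groupings are the pooled cohort plus each taxon. Eligibility follows
    :func:`coralrec.cohort.stratify`: one-habitat structures need ``n >=
    min_total`` colonies, two-habitat structures need ``>= min_per_habitat``
    in each substrate class. Ineligible pairs are recorded as skipped (blank
    cells); per-fit failures are recorded without aborting the grid.
    """
    eligibility = stratify(cohort, min_total=min_total, min_per_habitat=min_per_habitat)
    obs = derive_longevities(cohort)
    by_grouping: dict[str, list[LongevityObservation]] = {"All corals": obs}
    for taxon in cohort.taxa:
        by_grouping[taxon] = [o for o in obs if o.taxon == taxon]

    grid = FitGrid()
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    n_cells = len(by_grouping) * len(structures)
    children = iter(ss.spawn(n_cells))
    for grouping in eligibility.index:
        elig = eligibility.loc[grouping]
        for sid in structures:
            child = next(children)
            structure = _as_structure(sid)
            if not structure.habitat_split and not elig["eligible_single"]:
                grid.skipped.append((grouping, sid, f"n={elig['n_total']} < {min_total}"))
                continue
            if structure.habitat_split and not elig["eligible_split"]:
                grid.skipped.append(
                    (
                        grouping,
                        sid,
                        f"habitat n=({elig['n_unconsolidated']},{elig['n_consolidated']})"
                        f" below {min_per_habitat}",
                    )
                )
                continue
            try:
                res = SurvivorshipMLE(
                    by_grouping[grouping],
                    structure=structure,
                    window_years=cohort.window_years,
                    grouping=grouping,
                ).fit(seed=int(child.generate_state(1)[0] % (2**31)), n_restarts=n_restarts)
                grid.results[(grouping, sid)] = res
            except Exception as exc:  # record, never abort the grid
                grid.skipped.append((grouping, sid, f"fit failed: {exc}"))
    return grid
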