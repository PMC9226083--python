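"""Model comparison: likelihood-ratio tests for nested pairs, AIC over the grid.

The one-habitat constant model is nested in the one-habitat logistic model
(constant survival is the large-``b`` limit), so those two are compared with a
likelihood-ratio test; because the two-habitat structures are not all mutually
nested, the full grid is ranked by AIC, ``-2 ln L + 2 n``. The lowest-AIC
structure per grouping is best-supported; structures within two AIC units of
it have comparable support. The boundary nature of the constant-in-logistic
nesting can make the chi-square(1) reference conservative; the standard
reference is used regardless, and reported p-values should be read with that
in mind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .fitting import FitGrid, SurvivorshipResults

__all__ = ["NESTED_PAIRS", "LRTResult", "ModelComparisonTable", "aic", "lrt", "select"]

# (reduced, full) structure-id pairs where the reduced model is a special
# case (or boundary limit) of the full one
NESTED_PAIRS = frozenset({(1, 2), (3, 4), (3, 5), (3, 6), (4, 6), (5, 6)})

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def aic(fit: SurvivorshipResults) -> float:
    """Akaike information criterion ``-2 ln L + 2 n`` of a converged fit."""
    if not fit.converged:
        raise ValueError(
            f"AIC undefined for unconverged fit (grouping={fit.grouping!r}, "
            f"model={fit.structure.id})"
        )
    return -2.0 * fit.llf + 2.0 * fit.n_params


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a nested model pair."""

    chi2: float
    df: int
    p_value: float
    preferred: int
    reduced_id: int
    full_id: int
    alpha: float

    @property
    def stars(self) -> str:
        for level, mark in STAR_LEVELS:
            if self.p_value < level:
                return mark
        return "NS"


def lrt(
    reduced: SurvivorshipResults, full: SurvivorshipResults, alpha: float = 0.05
) -> LRTResult:
    """Likelihood-ratio test: ``chi2 = 2 (lnL_full - lnL_reduced)``.

    The p-value is the chi-square upper tail with degrees of freedom equal to
    the parameter-count difference. The full model is preferred when
    ``p < alpha``, else the reduced one.
    """
    pair = (reduced.structure.id, full.structure.id)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"structures {pair} are not a nested (reduced, full) pair")
    if reduced.grouping != full.grouping:
        raise ValueError(
            f"fits compare different groupings: {reduced.grouping!r} vs {full.grouping!r}"
        )
    chi2 = 2.0 * (full.llf - reduced.llf)
    if chi2 < -1e-6:
        raise ValueError(
            f"negative chi2 ({chi2:.3g}): the full-model optimiser failed to reach "
            "the reduced model's likelihood"
        )
    chi2 = max(chi2, 0.0)
    df = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(chi2, df))
    return LRTResult(
        chi2=chi2,
        df=df,
        p_value=p,
        preferred=full.structure.id if p < alpha else reduced.structure.id,
        reduced_id=reduced.structure.id,
        full_id=full.structure.id,
        alpha=alpha,
    )


@dataclass
class ModelComparisonTable:
    """AIC grid over structures (rows) and groupings (columns) with flags.

    ``best[g]`` is the lowest-AIC structure for grouping ``g`` (ties broken
    toward fewer parameters, then lower id); ``comparable[g]`` is the set of
    structures within ``delta`` AIC units of the best (always containing it).
    """

    aic_table: pd.DataFrame
    best: dict[str, int]
    comparable: dict[str, frozenset[int]]
    delta: float = 2.0
    lrt_results: dict[str, LRTResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.aic_table.copy()

    def render(self, decimals: int = 1) -> str:
        """Text table with ``**x**`` marking the best model per grouping and
        ``_x_`` marking others with comparable (delta-AIC < 2) support."""
        out = self.aic_table.copy().astype(object)
        for grouping in out.columns:
            for sid in out.index:
                v = self.aic_table.loc[sid, grouping]
                if pd.isna(v):
                    out.loc[sid, grouping] = "-"
                    continue
                cell = f"{v:.{decimals}f}"
                if sid == self.best[grouping]:
                    cell = f"**{cell}**"
                elif sid in self.comparable[grouping]:
                    cell = f"_{cell}_"
                out.loc[sid, grouping] = cell
        lines = [out.to_string()]
        if self.lrt_results:
            lines.append("")
            lines.append("Constant vs logistic (one habitat) likelihood-ratio tests:")
            for grouping, r in self.lrt_results.items():
                lines.append(
                    f"  {grouping}: chi2={r.chi2:.1f}, df={r.df}, "
                    f"p={r.p_value:.3g} {r.stars}"
                )
        return "\n".join(lines)


def select(
    fits: FitGrid | Iterable[SurvivorshipResults],
    delta: float = 2.0,
    alpha: float = 0.05,
    with_lrt: bool = True,
) -> ModelComparisonTable:
    """Rank fitted structures by AIC within each grouping.

    Accepts a :class:`FitGrid` or any iterable of results; unconverged fits
    are excluded. Where both one-habitat structures (1 and 2) converged for a
    grouping, their likelihood-ratio test is attached. The outcome does not
    depend on input ordering.
    """
    if isinstance(fits, FitGrid):
        results = list(fits.results.values())
    else:
        results = list(fits)
    results = [r for r in results if r.converged]
    if not results:
        raise ValueError("no converged fits to compare")

    by_grouping: dict[str, dict[int, SurvivorshipResults]] = {}
    for r in results:
        by_grouping.setdefault(r.grouping, {})[r.structure.id] = r

    groupings = sorted(by_grouping, key=lambda g: (g != "All corals", g))
    all_ids = sorted({r.structure.id for r in results})
    table = pd.DataFrame(index=pd.Index(all_ids, name="model_id"), columns=groupings, dtype=float)
    best: dict[str, int] = {}
    comparable: dict[str, frozenset[int]] = {}
    lrt_results: dict[str, LRTResult] = {}

    for grouping, cells in by_grouping.items():
        aics = {sid: aic(r) for sid, r in cells.items()}
        for sid, value in aics.items():
            table.loc[sid, grouping] = value
        best_id = min(
            aics, key=lambda sid: (aics[sid], cells[sid].n_params, sid)
        )
        best[grouping] = best_id
        comparable[grouping] = frozenset(
            sid for sid, value in aics.items() if value - aics[best_id] < delta
        )
        if with_lrt and 1 in cells and 2 in cells:
            lrt_results[grouping] = lrt(cells[1], cells[2], alpha=alpha)

    return ModelComparisonTable(
        aic_table=table,
        best=best,
        comparable=comparable,
        delta=delta,
        lrt_results=lrt_results,
    )
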