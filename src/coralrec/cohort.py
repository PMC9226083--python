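"""Colony fate tables: reading, validation, longevity derivation, stratification.

The unit of data is a fate-tracked colony: detected alive at an initial annual
survey (year 0) and assigned at each later survey to one of three categories —
``alive`` (living tissue present), ``dead`` (skeleton present without living
tissue), or ``lost`` (colony dislodged and gone). Both terminal categories are
mortality for modelling; the distinction is kept only for fate summaries.

Two delimited-text schemas are supported:

* ``status-long``: columns ``colony_id, taxon, habitat, status_y0..status_yT``
  with tokens ``alive|dead|lost``;
* ``longevity-wide``: columns ``colony_id, taxon, habitat, longevity,
  censored, terminal_fate``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FateRecord",
    "LongevityObservation",
    "CohortTable",
    "SchemaError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "derive_longevities",
    "fate_summary",
    "stratify",
]

STATUS_TOKENS = ("alive", "dead", "lost")
HABITAT_TOKENS = ("consolidated", "unconsolidated")


class SchemaError(ValueError):
    """A fate-table file does not match the documented column schema."""


class CohortValidationError(ValueError):
    """A fate record violates a cohort invariant (e.g. resurrection)."""


@dataclass(frozen=True)
class FateRecord:
    """One colony's identity, strata, and annual status sequence.

    ``statuses`` holds one token per survey, starting with the detection year
    (always ``alive``); once ``dead`` or ``lost`` appears, all later entries
    must repeat that terminal state — no resurrection.
    """

    colony_id: str
    taxon: str
    habitat: str
    statuses: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.habitat not in HABITAT_TOKENS:
            raise CohortValidationError(
                f"colony {self.colony_id}: habitat must be one of {HABITAT_TOKENS}, "
                f"got {self.habitat!r}"
            )
        if len(self.statuses) < 2:
            raise CohortValidationError(
                f"colony {self.colony_id}: need at least 2 surveys, got {len(self.statuses)}"
            )
        for tok in self.statuses:
            if tok not in STATUS_TOKENS:
                raise CohortValidationError(
                    f"colony {self.colony_id}: unknown status token {tok!r}"
                )
        if self.statuses[0] != "alive":
            raise CohortValidationError(
                f"colony {self.colony_id}: first survey status must be 'alive' "
                "(detection conditioning)"
            )
        terminal = None
        for tok in self.statuses[1:]:
            if terminal is not None and tok != terminal:
                raise CohortValidationError(
                    f"colony {self.colony_id}: status sequence is not monotone "
                    f"(resurrection after {terminal!r})"
                )
            if tok in ("dead", "lost"):
                terminal = tok

    @property
    def window_years(self) -> int:
        return len(self.statuses) - 1

    @property
    def terminal_fate(self) -> str:
        """Final category: ``alive`` if never terminal, else ``dead``/``lost``."""
        return self.statuses[-1]

    @property
    def longevity(self) -> int:
        """Complete annual intervals survived (censored at the window length)."""
        for year, tok in enumerate(self.statuses):
            if tok != "alive":
                return year - 1
        return self.window_years

    @property
    def censored(self) -> bool:
        return self.statuses[-1] == "alive"


@dataclass(frozen=True)
class LongevityObservation:
    """Integer years survived plus censoring flag — the likelihood's unit datum."""

    longevity: int
    censored: bool
    taxon: str
    habitat: str

    def __post_init__(self) -> None:
        if self.longevity < 0:
            raise CohortValidationError(f"longevity must be non-negative, got {self.longevity}")


@dataclass(frozen=True)
class CohortTable:
    """A validated collection of fate records sharing one survey window."""

    records: tuple[FateRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise CohortValidationError("cohort is empty")
        ids = [r.colony_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate colony_id values: {dupes[:5]}")
        windows = {r.window_years for r in records}
        if len(windows) > 1:
            raise CohortValidationError(
                f"records mix survey window lengths: {sorted(windows)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def window_years(self) -> int:
        return self.records[0].window_years

    @property
    def taxa(self) -> list[str]:
        """Distinct taxa in decreasing order of initial abundance."""
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.taxon] = counts.get(r.taxon, 0) + 1
        return sorted(counts, key=lambda t: (-counts[t], t))

    def subset(self, taxon: str | None = None, habitat: str | None = None) -> "CohortTable":
        recs = [
            r
            for r in self.records
            if (taxon is None or r.taxon == taxon)
            and (habitat is None or r.habitat == habitat)
        ]
        return CohortTable(tuple(recs))

    def to_status_frame(self) -> pd.DataFrame:
        T = self.window_years
        rows = [
            {
                "colony_id": r.colony_id,
                "taxon": r.taxon,
                "habitat": r.habitat,
                **{f"status_y{y}": r.statuses[y] for y in range(T + 1)},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def to_longevity_frame(self) -> pd.DataFrame:
        rows = [
            {
                "colony_id": r.colony_id,
                "taxon": r.taxon,
                "habitat": r.habitat,
                "longevity": r.longevity,
                "censored": r.censored,
                "terminal_fate": r.terminal_fate,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


def _norm(token: str) -> str:
    return str(token).strip().lower()


def read_cohort(path, format: str = "status-long", window_years: int | None = None) -> CohortTable:
    """Read and validate a colony fate table.

    Parameters
    ----------
    path : path-like
        CSV file in one of the two documented schemas.
    format : {"status-long", "longevity-wide"}
        ``status-long`` carries the raw annual status tokens; ``longevity-wide``
        carries derived longevity/censoring from which the (monotone) status
        sequence is reconstructed.
    window_years : int, optional
        Survey window length for ``longevity-wide`` input; defaults to the
        maximum longevity present (censored colonies sit at the window bound).

    Status and habitat tokens are normalised case-insensitively; taxon labels
    are taken verbatim.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]

    if format == "status-long":
        return _cohort_from_status_frame(df, source=str(path))
    if format == "longevity-wide":
        return _cohort_from_longevity_frame(df, window_years=window_years, source=str(path))
    raise ValueError(f"unknown fate-table format {format!r}")


def _cohort_from_status_frame(df: pd.DataFrame, source: str = "<frame>") -> CohortTable:
    for col in ("colony_id", "taxon", "habitat"):
        if col not in df.columns:
            raise SchemaError(f"{source}: missing required column {col!r}")
    status_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"status_y\d+", c)),
        key=lambda c: int(c.split("y")[-1]),
    )
    if not status_cols:
        raise SchemaError(f"{source}: no status_y0..status_yT columns found")
    expected = [f"status_y{y}" for y in range(len(status_cols))]
    if status_cols != expected:
        raise SchemaError(
            f"{source}: status columns must be contiguous status_y0..status_yT, got {status_cols}"
        )

    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict()
        statuses = []
        for col in status_cols:
            tok = _norm(row[col])
            if tok not in STATUS_TOKENS:
                raise SchemaError(
                    f"{source}, line {idx}: unknown status token {row[col]!r} in {col}"
                )
            statuses.append(tok)
        records.append(
            FateRecord(
                colony_id=str(row["colony_id"]).strip(),
                taxon=str(row["taxon"]).strip(),
                habitat=_norm(row["habitat"]),
                statuses=tuple(statuses),
            )
        )
    return CohortTable(tuple(records))


def _cohort_from_longevity_frame(
    df: pd.DataFrame, window_years: int | None, source: str = "<frame>"
) -> CohortTable:
    required = ("colony_id", "taxon", "habitat", "longevity", "censored", "terminal_fate")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{source}: missing required column {col!r}")
    longevities = df["longevity"].astype(int)
    T = int(longevities.max()) if window_years is None else int(window_years)

    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        t = int(row["longevity"])
        censored = _norm(row["censored"]) in ("true", "1", "yes")
        fate = _norm(row["terminal_fate"])
        if fate not in STATUS_TOKENS:
            raise SchemaError(
                f"{source}, line {idx}: unknown terminal_fate token {row['terminal_fate']!r}"
            )
        if censored != (fate == "alive"):
            raise CohortValidationError(
                f"{source}, line {idx}: censored flag inconsistent with terminal_fate"
            )
        if censored:
            statuses = ("alive",) * (T + 1)
        else:
            if t >= T:
                raise CohortValidationError(
                    f"{source}, line {idx}: uncensored longevity {t} >= window {T}"
                )
            statuses = ("alive",) * (t + 1) + (fate,) * (T - t)
        records.append(
            FateRecord(
                colony_id=str(row["colony_id"]).strip(),
                taxon=str(row["taxon"]).strip(),
                habitat=_norm(row["habitat"]),
                statuses=statuses,
            )
        )
    return CohortTable(tuple(records))


def write_cohort(cohort: CohortTable, path, format: str = "status-long") -> None:
    """Write a cohort table as UTF-8, comma-delimited CSV with a header row."""
    path = Path(path)
    if format == "status-long":
        df = cohort.to_status_frame()
    elif format == "longevity-wide":
        df = cohort.to_longevity_frame()
    else:
        raise ValueError(f"unknown fate-table format {format!r}")
    df.to_csv(path, index=False)


def derive_longevities(cohort: CohortTable) -> list[LongevityObservation]:
    """Censored longevity observations for every colony in the cohort.

    A colony alive at all ``T+1`` surveys yields ``(longevity=T,
    censored=True)``; a colony first seen terminal at survey ``t`` survived
    ``t-1`` complete intervals. ``dead`` and ``lost`` both count as mortality.
    """
    return [
        LongevityObservation(
            longevity=r.longevity, censored=r.censored, taxon=r.taxon, habitat=r.habitat
        )
        for r in cohort
    ]


def fate_summary(cohort: CohortTable, by: str = "all") -> pd.DataFrame:
    """Terminal fate proportions (alive / dead / lost) with initial counts.

    Parameters
    ----------
    by : {"all", "taxon"}
        Pool the cohort or summarise per taxon (ordered by decreasing
        abundance). Proportions refer to the final survey and sum to 1.
    """
    if by not in ("all", "taxon"):
        raise ValueError("by must be 'all' or 'taxon'")
    groups = [("all", list(cohort))] if by == "all" else [
        (taxon, [r for r in cohort if r.taxon == taxon]) for taxon in cohort.taxa
    ]
    rows = []
    for name, recs in groups:
        if not recs:
            logger.warning("fate_summary: empty group %r omitted", name)
            continue
        n = len(recs)
        fates = [r.terminal_fate for r in recs]
        rows.append(
            {
                "group": name,
                "n_initial": n,
                "alive": fates.count("alive") / n,
                "dead": fates.count("dead") / n,
                "lost": fates.count("lost") / n,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def stratify(
    cohort: CohortTable, min_total: int = 10, min_per_habitat: int = 5
) -> pd.DataFrame:
    """Eligibility of each grouping for one- and two-habitat model fits.

    One row per grouping (the pooled cohort first, then each taxon by
    decreasing abundance) with sample sizes and two flags:
    ``eligible_single`` (total ``n >= min_total``, Models 1-2) and
    ``eligible_split`` (both habitats ``>= min_per_habitat``, Models 3-6).
    Ineligible groupings mirror the blank cells of a model-comparison table.
    """
    if min_total <= 0 or min_per_habitat <= 0:
        raise ValueError("eligibility thresholds must be positive")
    groups = [("All corals", list(cohort))] + [
        (taxon, [r for r in cohort if r.taxon == taxon]) for taxon in cohort.taxa
    ]
    rows = []
    for name, recs in groups:
        n = len(recs)
        n_cons = sum(r.habitat == "consolidated" for r in recs)
        n_uncons = n - n_cons
        rows.append(
            {
                "grouping": name,
                "n_total": n,
                "n_consolidated": n_cons,
                "n_unconsolidated": n_uncons,
                "eligible_single": n >= min_total,
                "eligible_split": min(n_cons, n_uncons) >= min_per_habitat,
            }
        )
    return pd.DataFrame(rows).set_index("grouping")
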