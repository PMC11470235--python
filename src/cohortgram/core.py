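"""The chronogram table abstraction.

A *chronogram* is a dense long-format table with exactly one row per
{participant, calendar day} over an inclusive date span.  Per-participant
constant attributes (group labels, dose dates) are broadcast across each
participant's rows; sparse, date-stamped assay results sit on their
observation days and are missing elsewhere; derived annotation columns
(episode numbers, cumulative exposure counts, antigenic histories) are
tracked in an explicit registry so that summaries and serialization can
classify column roles.

The container is a thin wrapper around a :class:`pandas.DataFrame` plus
the attribute slots that every other operation in the package consumes:
the declared id/date column names, the metadata column registry, the
annotation registry, and the inclusive date span.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import pandas as pd

from ._errors import MissingColumnError, NonconstantMetadataError

__all__ = [
    "ChronogramTable",
    "Violation",
    "ValidationReport",
    "SummaryReport",
    "as_day",
    "validate",
    "collapse_metadata",
    "summarize",
]


def as_day(value) -> pd.Timestamp:
    """Coerce a scalar to a timezone-free, midnight-normalized day."""
    ts = pd.Timestamp(value)
    if ts.tz is not None:
        ts = ts.tz_localize(None)
    return ts.normalize()


def _na_safe_equal(a, b) -> bool:
    if pd.isna(a) and pd.isna(b):
        return True
    if pd.isna(a) or pd.isna(b):
        return False
    return a == b


@dataclass(eq=False)
class ChronogramTable:
    """Dense per-participant-per-day table with declared key columns.

    Parameters
    ----------
    data
        The underlying long-format frame.  Rows are kept in canonical
        order: participants in first-appearance order, dates ascending
        within each participant, with a fresh RangeIndex.
    id_col, date_col
        Names of the participant-identifier and calendar-date columns.
    metadata_cols
        Columns that are constant per participant (group labels, dose
        dates).  Everything else apart from the keys and the annotation
        registry is treated as experiment data.
    annotation_cols
        Columns produced by this package's annotation operations.
    date_span
        Inclusive ``(start, end)`` of the day grid.  Inferred from the
        data when omitted.
    is_view
        True for sub-cohort views, which are allowed to violate the
        dense-grid invariant (key uniqueness still holds).
    provenance
        Audit trail of filter/window/select steps applied to a view.
    vaccine_dose_cols
        Ordered dose-date metadata columns, recorded when
        ``vaccines_count`` runs so later annotations can reuse them.
    dense_defaults
        Registry of annotation columns that are dense step functions
        (cumulative counts, history strings); maps column name to the
        value the column takes before its first change.  Used by the
        sparse serializer.
    """

    data: pd.DataFrame
    id_col: str
    date_col: str
    metadata_cols: list[str] = field(default_factory=list)
    annotation_cols: list[str] = field(default_factory=list)
    date_span: Optional[tuple[pd.Timestamp, pd.Timestamp]] = None
    is_view: bool = False
    provenance: list[str] = field(default_factory=list)
    vaccine_dose_cols: Optional[list[str]] = None
    dense_defaults: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        for col, what in ((self.id_col, "id"), (self.date_col, "date")):
            if col not in self.data.columns:
                raise MissingColumnError(
                    f"{what} column '{col}' is absent from the table"
                )
        if self.date_span is not None:
            self.date_span = (as_day(self.date_span[0]), as_day(self.date_span[1]))
        elif len(self.data):
            dates = self.data[self.date_col]
            self.date_span = (as_day(dates.min()), as_day(dates.max()))

    # -- convenience accessors -------------------------------------------------

    @property
    def participants(self) -> np.ndarray:
        """Participant identifiers in first-appearance order."""
        return self.data[self.id_col].unique()

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_days(self) -> int:
        if self.date_span is None:
            return 0
        return (self.date_span[1] - self.date_span[0]).days + 1

    @property
    def experiment_cols(self) -> list[str]:
        reserved = {self.id_col, self.date_col}
        reserved.update(self.metadata_cols)
        reserved.update(self.annotation_cols)
        return [c for c in self.data.columns if c not in reserved]

    def replace(self, **changes) -> "ChronogramTable":
        """Return a copy with the given fields replaced; lists are copied."""
        current = dict(
            data=self.data,
            id_col=self.id_col,
            date_col=self.date_col,
            metadata_cols=list(self.metadata_cols),
            annotation_cols=list(self.annotation_cols),
            date_span=self.date_span,
            is_view=self.is_view,
            provenance=list(self.provenance),
            vaccine_dose_cols=(
                None if self.vaccine_dose_cols is None else list(self.vaccine_dose_cols)
            ),
            dense_defaults=dict(self.dense_defaults),
        )
        current.update(changes)
        return ChronogramTable(**current)

    def validate(self) -> "ValidationReport":
        return validate(self)

    def summarize(self) -> "SummaryReport":
        return summarize(self)

    def collapse_metadata(self) -> pd.DataFrame:
        return collapse_metadata(self)

    def __repr__(self):  # pragma: no cover - cosmetic
        span = (
            "empty"
            if self.date_span is None
            else f"{self.date_span[0].date()}..{self.date_span[1].date()}"
        )
        kind = "view" if self.is_view else "chronogram"
        return (
            f"<ChronogramTable {kind}: {self.n_participants} participants, "
            f"span {span}, {len(self.data)} rows>"
        )


@dataclass(frozen=True)
class Violation:
    rule_id: str
    participant: Optional[object]
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate(cg: ChronogramTable) -> ValidationReport:
    """Check a chronogram against its structural invariants.

    Returns a report listing every violation; never modifies the input.
    For sub-cohort views the dense-grid requirement is relaxed but key
    uniqueness and metadata constancy still apply.
    """
    violations: list[Violation] = []
    df = cg.data
    id_col, date_col = cg.id_col, cg.date_col

    # key uniqueness
    dup_mask = df.duplicated([id_col, date_col], keep="first")
    if dup_mask.any():
        dups = df.loc[dup_mask, [id_col, date_col]].drop_duplicates()
        for pid, d in dups.itertuples(index=False):
            day = as_day(d).date() if not pd.isna(d) else d
            violations.append(
                Violation("duplicate_key", pid, f"{{{pid}, {day}}} appears more than once")
            )

    # registry sanity
    for c in cg.metadata_cols:
        if c not in df.columns:
            violations.append(
                Violation("unknown_metadata_column", None, f"registered metadata column '{c}' missing")
            )
    present_meta = [c for c in cg.metadata_cols if c in df.columns]

    # dense grid: every participant covers every day of the span exactly once
    if not cg.is_view and len(df) and cg.date_span is not None:
        start, end = cg.date_span
        n_days = cg.n_days
        grp = df.groupby(id_col, sort=False)[date_col]
        agg = grp.agg(["min", "max", "nunique", "size"])
        for pid, row in agg.iterrows():
            if (
                row["nunique"] != n_days
                or as_day(row["min"]) != start
                or as_day(row["max"]) != end
            ):
                violations.append(
                    Violation(
                        "incomplete_grid",
                        pid,
                        f"{row['nunique']} distinct days over "
                        f"{as_day(row['min']).date()}..{as_day(row['max']).date()}, "
                        f"expected {n_days} days over {start.date()}..{end.date()}",
                    )
                )

    # metadata constancy: at most one distinct non-missing value, no partial missingness
    if len(df):
        grp = df.groupby(id_col, sort=False)
        for c in present_meta:
            nun = grp[c].nunique(dropna=True)
            nonmiss = grp[c].count()
            size = grp[c].size()
            bad = nun[nun > 1]
            for pid, k in bad.items():
                violations.append(
                    Violation(
                        "nonconstant_metadata",
                        pid,
                        f"column '{c}' takes {k} distinct values for participant {pid}",
                    )
                )
            partial = nonmiss[(nonmiss > 0) & (nonmiss < size)]
            for pid in partial.index:
                if pid in bad.index:
                    continue
                violations.append(
                    Violation(
                        "nonconstant_metadata",
                        pid,
                        f"column '{c}' is partially missing for participant {pid}",
                    )
                )

    return ValidationReport(tuple(violations))


def collapse_metadata(cg: ChronogramTable) -> pd.DataFrame:
    """Collapse to one row per participant carrying the metadata columns.

    Row order is the first-appearance order of participants.  Raises
    :class:`NonconstantMetadataError` if a metadata column takes more
    than one distinct non-missing value for some participant.
    """
    cols = [c for c in cg.metadata_cols if c in cg.data.columns]
    if not len(cg.data):
        return cg.data[[cg.id_col] + cols].copy().reset_index(drop=True)
    grp = cg.data.groupby(cg.id_col, sort=False)
    for c in cols:
        nun = grp[c].nunique(dropna=True)
        bad = nun[nun > 1]
        if len(bad):
            pid = bad.index[0]
            raise NonconstantMetadataError(
                f"metadata column '{c}' takes {bad.iloc[0]} distinct values "
                f"for participant {pid}"
            )
    out = grp[cols].first() if cols else grp.size().to_frame().drop(columns=0)
    out = out.reset_index()
    return out[[cg.id_col] + cols]


@dataclass(frozen=True)
class SummaryReport:
    n_participants: int
    date_span: Optional[tuple[pd.Timestamp, pd.Timestamp]]
    n_rows: int
    columns_by_role: dict[str, list[str]]
    non_missing: dict[str, int]

    def render(self) -> str:
        """Fixed-order human-readable rendering (used by the CLI)."""
        if self.date_span is None:
            span = "empty"
        else:
            span = f"{self.date_span[0].date()} .. {self.date_span[1].date()}"
        lines = [
            "chronogram summary",
            f"  participants: {self.n_participants}",
            f"  date span:    {span}",
            f"  rows:         {self.n_rows}",
        ]
        for role in ("metadata", "experiment", "annotation"):
            cols = self.columns_by_role.get(role, [])
            rendered = ", ".join(
                f"{c} ({self.non_missing.get(c, 0)} non-missing)" for c in cols
            )
            lines.append(f"  {role} columns: {rendered if rendered else '(none)'}")
        return "\n".join(lines)


def summarize(cg: ChronogramTable) -> SummaryReport:
    """Build a summary: counts, span, and columns classified by role."""
    non_missing = {c: int(cg.data[c].notna().sum()) for c in cg.data.columns}
    roles = {
        "metadata": [c for c in cg.metadata_cols if c in cg.data.columns],
        "experiment": cg.experiment_cols,
        "annotation": [c for c in cg.annotation_cols if c in cg.data.columns],
    }
    return SummaryReport(
        n_participants=cg.n_participants,
        date_span=cg.date_span,
        n_rows=len(cg.data),
        columns_by_role=roles,
        non_missing=non_missing,
    )


def chronograms_equal(a: ChronogramTable, b: ChronogramTable) -> bool:
    """Cell-, attribute-, and registry-exact equality of two chronograms."""
    attrs_equal = (
        a.id_col == b.id_col
        and a.date_col == b.date_col
        and list(a.metadata_cols) == list(b.metadata_cols)
        and list(a.annotation_cols) == list(b.annotation_cols)
        and a.date_span == b.date_span
        and a.is_view == b.is_view
        and list(a.provenance) == list(b.provenance)
        and a.vaccine_dose_cols == b.vaccine_dose_cols
        and set(a.dense_defaults) == set(b.dense_defaults)
        and all(_na_safe_equal(a.dense_defaults[k], b.dense_defaults[k]) for k in a.dense_defaults)
    )
    if not attrs_equal:
        return False
    if list(a.data.columns) != list(b.data.columns):
        return False
    try:
        pd.testing.assert_frame_equal(
            a.data.reset_index(drop=True), b.data.reset_index(drop=True)
        )
    except AssertionError:
        return False
    return True
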