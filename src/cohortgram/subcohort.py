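"""The filter → window → select grammar for extracting analysis sub-cohorts.

Sub-cohorting turns a biological question ("antibody levels 28-35 days
after the second dose, in people with four vaccine exposures and no
infection") into three mechanical steps: *filter* rows by a predicate
over columns, *window* each participant's timeline to signed day
offsets around a per-participant reference event (a metadata date, an
episode onset, or the n-th study visit), and *select* a single visit
per participant so no individual contributes more than one result.

Window offsets are inclusive at both ends and signed, so "the fortnight
before" is just ``(-14, -1)``.  Participants that lack the reference
event are dropped with a logged count — narrowing is the point of
sub-cohorting — and every step appends a provenance note to the view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import (
    AnnotationOrderError,
    MissingColumnError,
    SubcohortError,
    WindowError,
)
from .core import ChronogramTable, as_day

__all__ = [
    "WindowSpec",
    "filter_rows",
    "window_by_metadata",
    "window_by_episode",
    "window_by_visit",
    "select_visit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """A signed inclusive day window around a per-participant reference.

    ``reference`` names a metadata date column (the usual case), an
    episode ordinal, or a visit ordinal depending on which windowing
    function consumes the spec.
    """

    reference: object
    offset_lo: int
    offset_hi: int

    def __post_init__(self):
        if self.offset_lo > self.offset_hi:
            raise WindowError(
                f"offset_lo ({self.offset_lo}) must be <= offset_hi ({self.offset_hi})"
            )


def _as_view(cg: ChronogramTable, data: pd.DataFrame, note: str) -> ChronogramTable:
    return cg.replace(
        data=data.reset_index(drop=True),
        is_view=True,
        provenance=list(cg.provenance) + [note],
    )


def filter_rows(cg: ChronogramTable, predicate) -> ChronogramTable:
    """Retain rows satisfying a predicate (query string or callable).

    String predicates use :meth:`pandas.DataFrame.query` syntax, e.g.
    ``"exposures_count == 4 and episodes_count == 0"``.  A callable
    receives the frame and must return a boolean mask.  The result is a
    sub-cohort view: key uniqueness is kept but the dense grid is not.
    """
    df = cg.data
    if callable(predicate):
        mask = np.asarray(predicate(df), dtype=bool)
        if mask.shape != (len(df),):
            raise SubcohortError("predicate callable must return one boolean per row")
        out = df[mask]
        note = f"filter: <callable {getattr(predicate, '__name__', 'predicate')}>"
    else:
        try:
            out = df.query(str(predicate))
        except pd.errors.UndefinedVariableError as exc:
            raise MissingColumnError(f"filter references an unknown column: {exc}") from exc
        note = f"filter: {predicate}"
    return _as_view(cg, out, note)


def _apply_window(cg, ref_by_pid: "pd.Series", offset_lo, offset_hi, note, kind):
    if offset_lo > offset_hi:
        raise WindowError(f"offset_lo ({offset_lo}) must be <= offset_hi ({offset_hi})")
    df = cg.data
    n_total = cg.n_participants
    ref_by_pid = ref_by_pid.dropna()
    dropped = n_total - len(ref_by_pid)
    if dropped:
        logger.info("%s: dropped %d participant(s) lacking the reference", kind, dropped)
    refs = df[cg.id_col].map(ref_by_pid)
    lo = pd.to_timedelta(int(offset_lo), unit="D")
    hi = pd.to_timedelta(int(offset_hi), unit="D")
    keep = refs.notna() & (df[cg.date_col] >= refs + lo) & (df[cg.date_col] <= refs + hi)
    return _as_view(cg, df[keep], note)


def window_by_metadata(
    cg: ChronogramTable, ref_col: str, offset_lo: int, offset_hi: int
) -> ChronogramTable:
    """Window each participant to [ref + offset_lo, ref + offset_hi] days.

    ``ref_col`` is a metadata date column (e.g. the second-dose date, so
    offsets (28, 35) give the classic post-dose-2 peak window).
    Participants with a missing reference are dropped and logged.
    """
    if ref_col not in cg.data.columns:
        raise MissingColumnError(f"window reference column '{ref_col}' not found")
    meta = cg.collapse_metadata() if ref_col in cg.metadata_cols else None
    if meta is not None:
        refs = pd.Series(
            pd.to_datetime(meta[ref_col]).to_numpy(), index=meta[cg.id_col]
        )
    else:
        # fall back to per-participant first non-missing value
        refs = (
            cg.data.groupby(cg.id_col, sort=False)[ref_col].first().pipe(pd.to_datetime)
        )
    return _apply_window(
        cg,
        refs,
        offset_lo,
        offset_hi,
        f"window_by_metadata: {ref_col} [{offset_lo}, {offset_hi}]",
        "window_by_metadata",
    )


def window_by_episode(
    cg: ChronogramTable, episode_ordinal: int, offset_lo: int, offset_hi: int
) -> ChronogramTable:
    """Window around the start date of each participant's n-th episode."""
    if episode_ordinal < 1:
        raise WindowError("episode_ordinal must be >= 1")
    for c in ("episode_number", "episode_start"):
        if c not in cg.data.columns:
            raise AnnotationOrderError("run episodes_find before window_by_episode")
    df = cg.data
    starts = df[
        df["episode_start"].astype(bool)
        & (df["episode_number"] == episode_ordinal)
    ]
    refs = pd.Series(
        starts[cg.date_col].to_numpy(), index=starts[cg.id_col]
    )
    refs = refs.reindex(pd.Index(cg.participants))
    return _apply_window(
        cg,
        refs,
        offset_lo,
        offset_hi,
        f"window_by_episode: episode {episode_ordinal} [{offset_lo}, {offset_hi}]",
        "window_by_episode",
    )


def window_by_visit(
    cg: ChronogramTable,
    visit_col: str,
    visit_ordinal: int,
    offset_lo: int,
    offset_hi: int,
) -> ChronogramTable:
    """Window around the date of the n-th non-missing entry of ``visit_col``.

    Visits are ordered chronologically per participant; participants
    with fewer than ``visit_ordinal`` visits are dropped and logged.
    """
    if visit_ordinal < 1:
        raise WindowError("visit_ordinal must be >= 1")
    if visit_col not in cg.data.columns:
        raise MissingColumnError(f"visit column '{visit_col}' not found")
    df = cg.data
    vis = df[df[visit_col].notna()]
    refs = {}
    for pid, sub in vis.groupby(cg.id_col, sort=False):
        dates = np.sort(sub[cg.date_col].to_numpy())
        if len(dates) >= visit_ordinal:
            refs[pid] = dates[visit_ordinal - 1]
    refs = pd.Series(refs, dtype="datetime64[ns]").reindex(pd.Index(cg.participants))
    return _apply_window(
        cg,
        refs,
        offset_lo,
        offset_hi,
        f"window_by_visit: {visit_col} #{visit_ordinal} [{offset_lo}, {offset_hi}]",
        "window_by_visit",
    )


def select_visit(
    cg: ChronogramTable,
    value_col: str,
    policy: str = "first",
    ref=None,
) -> ChronogramTable:
    """Keep at most one row per participant, chosen among non-missing values.

    Rows where ``value_col`` is missing are dropped first; participants
    with no value at all vanish from the output.  ``policy`` picks the
    surviving row: ``"first"`` (earliest date — the default, and
    deterministic), ``"last"``, or ``"nearest"`` which needs ``ref``
    (a metadata date column name, or a fixed date); distance ties break
    to the earlier date.
    """
    if value_col not in cg.data.columns:
        raise MissingColumnError(f"value column '{value_col}' not found")
    df = cg.data
    sub = df[df[value_col].notna()]
    if policy == "first":
        idx = sub.groupby(cg.id_col, sort=False)[cg.date_col].idxmin()
    elif policy == "last":
        idx = sub.groupby(cg.id_col, sort=False)[cg.date_col].idxmax()
    elif policy == "nearest":
        if ref is None:
            raise SubcohortError("policy 'nearest' requires a reference (ref=...)")
        if isinstance(ref, str) and ref in df.columns:
            refs = pd.to_datetime(sub[ref])
        else:
            refs = pd.Series(as_day(ref), index=sub.index)
        dist = (sub[cg.date_col] - refs).abs()
        # rows are date-ascending per participant, so idxmin takes the
        # earlier date on a distance tie
        idx = dist.groupby(sub[cg.id_col], sort=False).idxmin()
    else:
        raise SubcohortError(f"unknown select policy {policy!r}")
    out = df.loc[idx.to_numpy()]
    return _as_view(cg, out, f"select_visit: {value_col} policy={policy}")
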