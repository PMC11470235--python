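"""Infection-episode detection, seroconversion windows, filling, counting.

An *infection episode* is a maximal cluster of evidence days — days on
which any scanned column (symptom diary, PCR/antigen result, sequencing
call) matches a user-declared positive value — where consecutive
evidence days are no more than ``max_gap`` days apart.  The episode
spans from its first to its last evidence day, is numbered
chronologically per participant (1-based), and every day inside the
span carries the episode number.

Serological transitions are handled separately: the exposure window
implied by a negative→positive marker change between two blood draws is
usually far wider than a test-confirmed episode, so seroconversion
detection writes its own dedicated columns rather than reusing the
episode columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import (
    AnnotationOrderError,
    AnnotationStateError,
    FillConflictError,
    MissingColumnError,
    UnknownMarkerValueError,
)
from .core import ChronogramTable

__all__ = [
    "EvidenceSpec",
    "SeroconversionSpec",
    "episodes_find",
    "episodes_find_seroconversion",
    "episodes_fill",
    "episodes_count",
    "episodes_table",
    "seroconversions_table",
]

logger = logging.getLogger(__name__)

EPISODE_COLS = ("episode_number", "episode_start", "episode_end", "episode_evidence")
SERO_COLS = (
    "sero_episode_number",
    "sero_window_start",
    "sero_window_end",
    "baseline_seropositive",
    "sero_reversion",
)


def _norm(v) -> str:
    return str(v).strip().casefold()


@dataclass(frozen=True)
class EvidenceSpec:
    """Which columns to scan and which values count as positive evidence.

    ``scan`` maps a column name to the values that flag an evidence day
    in that column.  Matching is exact equality after trimming and
    case-folding unless ``regex=True``, in which case the entries are
    regular expressions applied with ``re.search`` semantics.
    """

    scan: Mapping[str, Sequence[str]]
    regex: bool = False

    def check(self, cg: ChronogramTable) -> None:
        if not self.scan:
            raise MissingColumnError("EvidenceSpec.scan must name at least one column")
        for col, values in self.scan.items():
            if col not in cg.data.columns:
                raise MissingColumnError(f"scan column '{col}' not found in chronogram")
            if not list(values):
                raise MissingColumnError(
                    f"scan column '{col}' has an empty match-value list"
                )


@dataclass(frozen=True)
class SeroconversionSpec:
    """Marker column plus its disjoint negative / positive value sets."""

    marker_col: str
    negative_values: Sequence[str] = ("negative",)
    positive_values: Sequence[str] = ("positive",)

    def check(self, cg: ChronogramTable) -> None:
        if self.marker_col not in cg.data.columns:
            raise MissingColumnError(
                f"marker column '{self.marker_col}' not found in chronogram"
            )
        neg = {_norm(v) for v in self.negative_values}
        pos = {_norm(v) for v in self.positive_values}
        if neg & pos:
            raise UnknownMarkerValueError(
                f"negative and positive value sets overlap: {sorted(neg & pos)}"
            )


def _match_mask(series: pd.Series, values, regex: bool) -> np.ndarray:
    out = np.zeros(len(series), dtype=bool)
    notna = series.notna().to_numpy()
    if not notna.any():
        return out
    vals = series[series.notna()].astype(str).str.strip()
    if regex:
        m = np.zeros(len(vals), dtype=bool)
        for pat in values:
            m |= vals.str.contains(pat, regex=True, na=False).to_numpy()
    else:
        targets = {_norm(v) for v in values}
        m = vals.str.casefold().isin(targets).to_numpy()
    out[np.flatnonzero(notna)] = m
    return out


def episodes_find(
    cg: ChronogramTable,
    spec: EvidenceSpec,
    max_gap: int = 7,
    *,
    overwrite: bool = False,
) -> ChronogramTable:
    """Merge evidence days into numbered infection episodes.

    Searches backwards and forwards in time per participant: evidence
    days whose consecutive gaps are all ``<= max_gap`` days form one
    episode spanning [first evidence day, last evidence day]; a larger
    gap starts a new episode.  ``max_gap`` defaults to 7 days and should
    be chosen per pathogen.  Adds the columns ``episode_number``
    (nullable Int64), ``episode_start`` / ``episode_end`` (bool, True on
    the span boundaries) and ``episode_evidence`` (which scanned columns
    matched on each evidence day).
    """
    if not isinstance(spec, EvidenceSpec):
        spec = EvidenceSpec(scan=spec)
    spec.check(cg)
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    present = [c for c in EPISODE_COLS if c in cg.data.columns]
    if present and not overwrite:
        raise AnnotationStateError(
            f"episode columns {present} already exist; pass overwrite=True to redo"
        )

    df = cg.data.drop(columns=present).reset_index(drop=True)
    n = len(df)
    col_masks = {
        col: _match_mask(df[col], values, spec.regex) for col, values in spec.scan.items()
    }
    any_mask = np.zeros(n, dtype=bool)
    for m in col_masks.values():
        any_mask |= m
    evidence = np.full(n, np.nan, dtype=object)
    for col in sorted(col_masks):
        for i in np.flatnonzero(col_masks[col]):
            evidence[i] = col if evidence[i] is np.nan else f"{evidence[i]};{col}"

    ep_num = np.full(n, np.nan)
    ep_start = np.zeros(n, dtype=bool)
    ep_end = np.zeros(n, dtype=bool)
    gap = np.timedelta64(int(max_gap), "D")
    for _, sub in df.groupby(cg.id_col, sort=False):
        pos = sub.index.to_numpy()
        m = any_mask[pos]
        if not m.any():
            continue
        dates = sub[cg.date_col].to_numpy()
        order = np.argsort(dates, kind="stable")
        dates_sorted = dates[order]
        pos_sorted = pos[order]
        m_sorted = m[order]
        evd = dates_sorted[m_sorted]
        breaks = np.flatnonzero((evd[1:] - evd[:-1]) > gap)
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(evd) - 1]
        for k, (si, ei) in enumerate(zip(starts, ends), start=1):
            s, e = evd[si], evd[ei]
            inside = (dates_sorted >= s) & (dates_sorted <= e)
            ep_num[pos_sorted[inside]] = k
            ep_start[pos_sorted[dates_sorted == s]] = True
            ep_end[pos_sorted[dates_sorted == e]] = True

    df["episode_number"] = pd.Series(ep_num).astype("Int64")
    df["episode_start"] = ep_start
    df["episode_end"] = ep_end
    df["episode_evidence"] = evidence
    # the boolean flags are dense (False almost everywhere); registering a
    # default lets the serializer store only their change points
    defaults = dict(cg.dense_defaults)
    defaults["episode_start"] = False
    defaults["episode_end"] = False
    return cg.replace(
        data=df,
        annotation_cols=[c for c in cg.annotation_cols if c not in EPISODE_COLS]
        + list(EPISODE_COLS),
        dense_defaults=defaults,
    )


def episodes_table(cg: ChronogramTable) -> pd.DataFrame:
    """Per-participant episode summary: ordinal, span, evidence tally."""
    for c in ("episode_number", "episode_start"):
        if c not in cg.data.columns:
            raise AnnotationOrderError("run episodes_find before episodes_table")
    df = cg.data
    ep_rows = df[df["episode_number"].notna()]
    if not len(ep_rows):
        return pd.DataFrame(
            columns=[cg.id_col, "episode_number", "start_date", "end_date", "evidence_summary"]
        )
    records = []
    for (pid, num), sub in ep_rows.groupby([cg.id_col, "episode_number"], sort=False):
        tally: dict[str, int] = {}
        for s in sub["episode_evidence"].dropna():
            for col in str(s).split(";"):
                tally[col] = tally.get(col, 0) + 1
        summary = ";".join(f"{k}:{v}" for k, v in sorted(tally.items()))
        records.append(
            {
                cg.id_col: pid,
                "episode_number": int(num),
                "start_date": sub[cg.date_col].min(),
                "end_date": sub[cg.date_col].max(),
                "evidence_summary": summary,
            }
        )
    return pd.DataFrame.from_records(records)


def episodes_find_seroconversion(
    cg: ChronogramTable,
    spec: SeroconversionSpec,
    *,
    overwrite: bool = False,
) -> ChronogramTable:
    """Detect negative→positive marker transitions between measurements.

    For each participant, every measurement pair (negative at one draw,
    positive at the next chronological draw) yields one seroconversion
    window ``(last_negative_date, first_positive_date]`` — half-open so
    a single date can never be both boundary kinds.  Participants whose
    first measurement is already positive are flagged baseline-positive
    and create no window; positive→negative reversion is flagged but
    never creates an episode.  Missing marker values are skipped, not
    treated as negative.

    Writes ``sero_episode_number``, ``sero_window_start`` and
    ``sero_window_end`` on rows inside each window, plus the
    per-participant flags ``baseline_seropositive`` and
    ``sero_reversion`` — deliberately distinct from the test-evidence
    episode columns.
    """
    spec.check(cg)
    present = [c for c in SERO_COLS if c in cg.data.columns]
    if present and not overwrite:
        raise AnnotationStateError(
            f"seroconversion columns {present} already exist; pass overwrite=True"
        )
    df = cg.data.drop(columns=present).reset_index(drop=True)
    n = len(df)
    neg = {_norm(v) for v in spec.negative_values}
    pos = {_norm(v) for v in spec.positive_values}

    marker = df[spec.marker_col]
    obs_mask = marker.notna().to_numpy()
    sero_num = np.full(n, np.nan)
    w_start = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    w_end = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    baseline = np.zeros(n, dtype=bool)
    reversion = np.zeros(n, dtype=bool)

    for pid, sub in df.groupby(cg.id_col, sort=False):
        pos_idx = sub.index.to_numpy()
        dates = sub[cg.date_col].to_numpy()
        order = np.argsort(dates, kind="stable")
        dates = dates[order]
        rows = pos_idx[order]
        m = obs_mask[rows]
        if not m.any():
            continue
        obs_rows = rows[m]
        obs_dates = dates[m]
        states = []
        for r in obs_rows:
            v = _norm(marker.iloc[r])
            if v in pos:
                states.append(True)
            elif v in neg:
                states.append(False)
            else:
                raise UnknownMarkerValueError(
                    f"unrecognized marker value {marker.iloc[r]!r} in column "
                    f"'{spec.marker_col}' for participant {df[cg.id_col].iloc[r]!r} "
                    f"on {pd.Timestamp(df[cg.date_col].iloc[r]).date()}"
                )
        if states[0]:
            baseline[rows] = True
        k = 0
        for i in range(len(states) - 1):
            if states[i] and not states[i + 1]:
                reversion[rows] = True
            if (not states[i]) and states[i + 1]:
                k += 1
                s, e = obs_dates[i], obs_dates[i + 1]
                inside = rows[(dates > s) & (dates <= e)]
                sero_num[inside] = k
                w_start[inside] = s
                w_end[inside] = e

    df["sero_episode_number"] = pd.Series(sero_num).astype("Int64")
    df["sero_window_start"] = w_start
    df["sero_window_end"] = w_end
    df["baseline_seropositive"] = baseline
    df["sero_reversion"] = reversion
    defaults = dict(cg.dense_defaults)
    defaults["baseline_seropositive"] = False
    defaults["sero_reversion"] = False
    return cg.replace(
        data=df,
        annotation_cols=[c for c in cg.annotation_cols if c not in SERO_COLS]
        + list(SERO_COLS),
        dense_defaults=defaults,
    )


def seroconversions_table(cg: ChronogramTable) -> pd.DataFrame:
    """Per-participant seroconversion windows as one row per window."""
    if "sero_episode_number" not in cg.data.columns:
        raise AnnotationOrderError(
            "run episodes_find_seroconversion before seroconversions_table"
        )
    df = cg.data
    rows = df[df["sero_episode_number"].notna()]
    records = []
    for (pid, num), sub in rows.groupby([cg.id_col, "sero_episode_number"], sort=False):
        records.append(
            {
                cg.id_col: pid,
                "sero_episode_number": int(num),
                "window_start": sub["sero_window_start"].iloc[0],
                "window_end": sub["sero_window_end"].iloc[0],
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[cg.id_col, "sero_episode_number", "window_start", "window_end"],
    )


def episodes_fill(
    cg: ChronogramTable,
    fill_cols: Sequence[str],
    policy: str = "error",
) -> ChronogramTable:
    """Broadcast an episode-level value over every day of each episode.

    For each episode and each column in ``fill_cols``, the non-missing
    values observed inside the episode span are reduced to a single
    value and written to a companion ``<col>_filled`` column on every
    day of the episode (so e.g. one sequencing day annotates the whole
    episode with its variant call).  ``policy`` controls conflicts when
    an episode holds several distinct values: ``"error"`` aborts,
    ``"first_nonmissing"`` takes the earliest-dated value.
    """
    if "episode_number" not in cg.data.columns:
        raise AnnotationOrderError("run episodes_find before episodes_fill")
    if policy not in ("error", "first_nonmissing"):
        raise ValueError(f"unknown fill policy {policy!r}")
    for c in fill_cols:
        if c not in cg.data.columns:
            raise MissingColumnError(f"fill column '{c}' not found in chronogram")

    df = cg.data.reset_index(drop=True)
    new_cols = []
    for c in fill_cols:
        target = f"{c}_filled"
        if target in df.columns:
            raise AnnotationStateError(f"column '{target}' already exists")
        arr = np.full(len(df), np.nan, dtype=object)
        ep_rows = df[df["episode_number"].notna()]
        for (pid, num), sub in ep_rows.groupby([cg.id_col, "episode_number"], sort=False):
            sub = sub.sort_values(cg.date_col, kind="stable")
            vals = sub[c].dropna()
            if not len(vals):
                continue
            distinct = vals.unique()
            if len(distinct) > 1 and policy == "error":
                raise FillConflictError(
                    f"episode {int(num)} of participant {pid!r} holds "
                    f"{len(distinct)} distinct values of '{c}': {list(distinct)}; "
                    f"use policy='first_nonmissing' to take the earliest"
                )
            arr[sub.index.to_numpy()] = vals.iloc[0]
        filled = pd.Series(arr, dtype=object)
        try:
            filled = filled.astype(df[c].dtype)
        except (TypeError, ValueError):
            pass
        df[target] = filled
        new_cols.append(target)
    return cg.replace(
        data=df, annotation_cols=list(cg.annotation_cols) + new_cols
    )


def episodes_count(cg: ChronogramTable) -> ChronogramTable:
    """Cumulative per-row count of episodes started on or before each day.

    The count increments on the episode start date itself and is
    monotone non-decreasing over each participant's timeline.  Episode
    detection must have run first — annotations build on each other, so
    their order of execution matters.
    """
    if "episode_start" not in cg.data.columns:
        raise AnnotationOrderError(
            "episodes_count requires episodes_find to have run first "
            "(annotations build on each other: their order matters)"
        )
    # rows are kept date-ascending within each participant by construction,
    # so a grouped cumulative sum of start flags is the running episode count
    df = cg.data.reset_index(drop=True)
    counts = (
        df.groupby(cg.id_col, sort=False)["episode_start"].cumsum().astype("int64")
    )
    df = df.assign(episodes_count=counts)
    defaults = dict(cg.dense_defaults)
    defaults["episodes_count"] = 0
    return cg.replace(
        data=df,
        annotation_cols=[c for c in cg.annotation_cols if c != "episodes_count"]
        + ["episodes_count"],
        dense_defaults=defaults,
    )
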