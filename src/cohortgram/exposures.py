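"""Cumulative vaccine/exposure counts and per-day antigenic histories.

An *exposure* is any antigenic encounter: a vaccine dose (dated by a
metadata dose-date column) or an infection episode (dated by its first
evidence day, or — for seroconversion-only detection — by the first
positive blood draw).  Counts increment on the event day itself, so
day 0 of a dose is post-dose; this ±1-day convention propagates into
every downstream window and is therefore fixed and documented here.

The antigenic history of a participant on day *t* is the chronological
sequence of exposure codes with event date <= t, joined by ":" —
vaccines as ``V1, V2, ...``, infections as ``I1`` or ``I1[label]`` when
a label column (e.g. a filled sequencing call) supplies a variant.
Same-day vaccine + infection ties order vaccine first (and are logged).
The string format is round-trip parseable with :func:`parse_history`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import (
    AnnotationOrderError,
    ChronogramError,
    DoseOrderError,
    MissingColumnError,
)
from .core import ChronogramTable, collapse_metadata
from .episodes import episodes_table, seroconversions_table

__all__ = [
    "ExposureEvent",
    "vaccines_count",
    "exposures_count",
    "antigenic_history",
    "exposure_events",
    "parse_history",
]

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^([VI])(\d+)(?:\[([^\]]*)\])?$")


@dataclass(frozen=True)
class ExposureEvent:
    kind: str  # "vaccine" | "infection"
    label: str
    event_date: pd.Timestamp


def vaccines_count(
    cg: ChronogramTable, dose_date_cols: Sequence[str]
) -> ChronogramTable:
    """Per-row count of vaccine doses received on or before each day.

    ``dose_date_cols`` is the ordered list of metadata columns holding
    dose dates (missing = dose not received).  Non-missing dose dates
    must be strictly increasing in the listed order for every
    participant.  The count increments on the dose date itself.
    """
    dose_date_cols = list(dose_date_cols)
    if not dose_date_cols:
        raise ChronogramError("dose_date_cols must name at least one column")
    for c in dose_date_cols:
        if c not in cg.data.columns:
            raise MissingColumnError(f"dose date column '{c}' not found")
        if c not in cg.metadata_cols:
            raise ChronogramError(
                f"dose date column '{c}' is not a registered metadata column"
            )

    meta = collapse_metadata(cg)
    for _, row in meta.iterrows():
        prev = None
        for c in dose_date_cols:
            d = row[c]
            if pd.isna(d):
                continue
            d = pd.Timestamp(d)
            if prev is not None and d <= prev:
                raise DoseOrderError(
                    f"participant {row[cg.id_col]!r}: dose date in '{c}' "
                    f"({d.date()}) is not after the previous dose ({prev.date()})"
                )
            prev = d

    df = cg.data.reset_index(drop=True)
    total = np.zeros(len(df), dtype="int64")
    for c in dose_date_cols:
        dose = pd.to_datetime(df[c])
        total += (dose.notna() & (dose <= df[cg.date_col])).to_numpy(dtype="int64")
    df = df.assign(vaccines_count=total)
    defaults = dict(cg.dense_defaults)
    defaults["vaccines_count"] = 0
    return cg.replace(
        data=df,
        annotation_cols=[c for c in cg.annotation_cols if c != "vaccines_count"]
        + ["vaccines_count"],
        vaccine_dose_cols=dose_date_cols,
        dense_defaults=defaults,
    )


def exposures_count(cg: ChronogramTable) -> ChronogramTable:
    """Row-wise total exposures = vaccines_count + episodes_count."""
    for c in ("vaccines_count", "episodes_count"):
        if c not in cg.data.columns:
            raise AnnotationOrderError(
                f"exposures_count requires '{c}' (run vaccines_count and "
                f"episodes_count first: annotation order matters)"
            )
    df = cg.data.reset_index(drop=True)
    df = df.assign(
        exposures_count=(df["vaccines_count"] + df["episodes_count"]).astype("int64")
    )
    defaults = dict(cg.dense_defaults)
    defaults["exposures_count"] = 0
    return cg.replace(
        data=df,
        annotation_cols=[c for c in cg.annotation_cols if c != "exposures_count"]
        + ["exposures_count"],
        dense_defaults=defaults,
    )


def exposure_events(
    cg: ChronogramTable,
    infection_label_col: Optional[str] = None,
    include_seroconversions: bool = False,
) -> pd.DataFrame:
    """All dated exposure events, one row each: {id, kind, label, event_date, code}.

    Vaccine events come from the dose columns recorded by
    ``vaccines_count``; infection events from episode start dates, plus
    (optionally) seroconversion windows that do not overlap any detected
    episode, dated at the first positive draw.  Codes number each kind
    chronologically per participant; same-day ties order vaccine first.
    """
    if cg.vaccine_dose_cols is None:
        raise AnnotationOrderError("run vaccines_count before building exposure events")
    if "episode_number" not in cg.data.columns:
        raise AnnotationOrderError("run episodes_find before building exposure events")
    if infection_label_col is not None and infection_label_col not in cg.data.columns:
        raise MissingColumnError(f"label column '{infection_label_col}' not found")

    meta = collapse_metadata(cg)
    eptab = episodes_table(cg)
    labels: dict[tuple, str] = {}
    if infection_label_col is not None and len(eptab):
        start_rows = cg.data[
            cg.data["episode_start"].fillna(False).astype(bool)
            & cg.data[infection_label_col].notna()
        ]
        for _, r in start_rows.iterrows():
            labels[(r[cg.id_col], int(r["episode_number"]))] = str(r[infection_label_col])

    sero_by_pid: dict = {}
    if include_seroconversions and "sero_episode_number" in cg.data.columns:
        st = seroconversions_table(cg)
        for _, r in st.iterrows():
            sero_by_pid.setdefault(r[cg.id_col], []).append(
                (pd.Timestamp(r["window_start"]), pd.Timestamp(r["window_end"]))
            )

    ep_by_pid: dict = {}
    for _, r in eptab.iterrows():
        ep_by_pid.setdefault(r[cg.id_col], []).append(r)

    records = []
    tie_days = 0
    for _, mrow in meta.iterrows():
        pid = mrow[cg.id_col]
        events = []  # (date, priority, kind, label)
        k = 0
        for c in cg.vaccine_dose_cols:
            d = mrow[c]
            if pd.isna(d):
                continue
            k += 1
            events.append((pd.Timestamp(d), 0, "vaccine", str(k)))
        inf_dates = []
        for r in ep_by_pid.get(pid, []):
            lab = labels.get((pid, int(r["episode_number"])))
            inf_dates.append((pd.Timestamp(r["start_date"]), lab))
        for ws, we in sero_by_pid.get(pid, []):
            overlapped = any(
                ws < d <= we for d, _ in inf_dates
            )
            if not overlapped:
                inf_dates.append((we, None))
        inf_dates.sort(key=lambda t: t[0])
        for j, (d, lab) in enumerate(inf_dates, start=1):
            events.append((d, 1, "infection", lab if lab is not None else ""))
        events.sort(key=lambda t: (t[0], t[1]))
        seen_dates = [e[0] for e in events]
        tie_days += len(seen_dates) - len(set(seen_dates))
        inf_idx = 0
        for d, _, kind, lab in events:
            if kind == "vaccine":
                code = f"V{lab}"
                label = ""
            else:
                inf_idx += 1
                code = f"I{inf_idx}[{lab}]" if lab else f"I{inf_idx}"
                label = lab
            records.append(
                {
                    cg.id_col: pid,
                    "kind": kind,
                    "label": label,
                    "event_date": d,
                    "code": code,
                }
            )
    if tie_days:
        logger.info(
            "%d same-day vaccine/infection tie(s); vaccine ordered first", tie_days
        )
    return pd.DataFrame.from_records(
        records, columns=[cg.id_col, "kind", "label", "event_date", "code"]
    )


def antigenic_history(
    cg: ChronogramTable,
    infection_label_col: Optional[str] = None,
    include_seroconversions: bool = False,
) -> ChronogramTable:
    """Annotate each row with the ":"-joined exposure codes accrued so far.

    The history on day *t* lists every exposure with event date <= *t*
    in chronological order; it is the empty string before the first
    exposure, and the history at any later day always extends (is
    prefixed by) the history at an earlier day.
    """
    events = exposure_events(
        cg,
        infection_label_col=infection_label_col,
        include_seroconversions=include_seroconversions,
    )
    df = cg.data.reset_index(drop=True)
    hist = np.full(len(df), "", dtype=object)
    ev_by_pid = {pid: sub for pid, sub in events.groupby(cg.id_col, sort=False)}
    for pid, sub in df.groupby(cg.id_col, sort=False):
        ev = ev_by_pid.get(pid)
        if ev is None or not len(ev):
            continue
        ev_dates = ev["event_date"].to_numpy()
        codes = ev["code"].tolist()
        prefixes = [""]
        for c in codes:
            prefixes.append(c if prefixes[-1] == "" else f"{prefixes[-1]}:{c}")
        rows = sub.index.to_numpy()
        k = np.searchsorted(ev_dates, sub[cg.date_col].to_numpy(), side="right")
        for r, kk in zip(rows, k):
            hist[r] = prefixes[kk]
    df = df.assign(antigenic_history=pd.Series(hist, dtype=object))
    defaults = dict(cg.dense_defaults)
    defaults["antigenic_history"] = ""
    return cg.replace(
        data=df,
        annotation_cols=[c for c in cg.annotation_cols if c != "antigenic_history"]
        + ["antigenic_history"],
        dense_defaults=defaults,
    )


def parse_history(history: str) -> list[dict]:
    """Parse a history string back into structured exposure records.

    ``"V1:I1[Delta]:V2"`` → vaccine 1, infection 1 labelled "Delta",
    vaccine 2.  The empty string parses to an empty list.
    """
    if history is None or history == "":
        return []
    out = []
    for token in str(history).split(":"):
        m = _CODE_RE.match(token)
        if not m:
            raise ValueError(f"malformed history code: {token!r}")
        kind, ordinal, label = m.groups()
        out.append(
            {
                "kind": "vaccine" if kind == "V" else "infection",
                "ordinal": int(ordinal),
                "label": label,
            }
        )
    return out
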