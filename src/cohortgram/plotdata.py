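"""Plot-ready tables for swimmers plots and titer trajectories.

Rendering is deliberately out of scope: these functions return tidy
frames that any plotting layer (matplotlib, ggplot, ...) can consume,
and everything downstream asserts on the tables, never on images.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import AnnotationOrderError, MissingColumnError
from .core import ChronogramTable, collapse_metadata
from .episodes import episodes_table
from .subcohort import WindowSpec

__all__ = ["swimmers_table", "trajectory_table"]

logger = logging.getLogger(__name__)


def swimmers_table(
    cg: ChronogramTable,
    visit_marker_col: str,
    shade_col: Optional[str] = None,
    *,
    dose_date_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One record per event (dose, visit, episode) per participant lane.

    ``visit_marker_col`` identifies venepuncture days (non-missing
    entries); ``shade_col`` supplies the value that shades each visit
    marker (e.g. anti-nucleocapsid IgG status).  Dose events come from
    the dose columns recorded by ``vaccines_count`` unless
    ``dose_date_cols`` overrides them.  Records are sorted by
    participant (first-appearance order) then date.
    """
    if visit_marker_col not in cg.data.columns:
        raise MissingColumnError(f"visit marker column '{visit_marker_col}' not found")
    if shade_col is not None and shade_col not in cg.data.columns:
        raise MissingColumnError(f"shade column '{shade_col}' not found")
    dose_cols = list(dose_date_cols) if dose_date_cols is not None else cg.vaccine_dose_cols
    if dose_cols is None:
        raise AnnotationOrderError(
            "no dose date columns: run vaccines_count first or pass dose_date_cols"
        )
    for c in dose_cols:
        if c not in cg.data.columns:
            raise MissingColumnError(f"dose date column '{c}' not found")

    records = []
    meta = collapse_metadata(cg)
    for _, row in meta.iterrows():
        pid = row[cg.id_col]
        for k, c in enumerate(dose_cols, start=1):
            d = row[c]
            if pd.isna(d):
                continue
            records.append(
                {
                    "participant": pid,
                    "date": pd.Timestamp(d),
                    "event_kind": "dose",
                    "label": str(k),
                    "shade_value": np.nan,
                }
            )
    visits = cg.data[cg.data[visit_marker_col].notna()]
    for _, r in visits.iterrows():
        records.append(
            {
                "participant": r[cg.id_col],
                "date": pd.Timestamp(r[cg.date_col]),
                "event_kind": "visit",
                "label": "",
                "shade_value": r[shade_col] if shade_col is not None else np.nan,
            }
        )
    if "episode_number" in cg.data.columns:
        for _, r in episodes_table(cg).iterrows():
            records.append(
                {
                    "participant": r[cg.id_col],
                    "date": pd.Timestamp(r["start_date"]),
                    "event_kind": "episode",
                    "label": str(int(r["episode_number"])),
                    "shade_value": np.nan,
                }
            )
    out = pd.DataFrame.from_records(
        records, columns=["participant", "date", "event_kind", "label", "shade_value"]
    )
    if not len(out):
        return out
    lane_order = {pid: i for i, pid in enumerate(cg.participants)}
    out["_lane"] = out["participant"].map(lane_order)
    out = out.sort_values(["_lane", "date"], kind="stable").drop(columns="_lane")
    return out.reset_index(drop=True)


def trajectory_table(
    cg: ChronogramTable,
    value_col: str,
    highlight_window: WindowSpec,
    *,
    facet_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-sample trajectory records with an in-window highlight flag.

    One record per non-missing ``value_col`` row, with ``highlighted``
    True iff the sample date falls inside the participant's resolved
    window (``highlight_window.reference`` names a metadata date column;
    offsets inclusive at both ends).  Participants whose reference date
    is missing keep their rows, un-highlighted, with a logged count.
    ``sample_index`` numbers consecutive samples per participant so a
    renderer can join them with a line.
    """
    if value_col not in cg.data.columns:
        raise MissingColumnError(f"value column '{value_col}' not found")
    ref_col = highlight_window.reference
    if ref_col not in cg.data.columns:
        raise MissingColumnError(f"window reference column '{ref_col}' not found")
    for c in facet_cols:
        if c not in cg.data.columns:
            raise MissingColumnError(f"facet column '{c}' not found")

    df = cg.data
    sub = df[df[value_col].notna()]
    refs = pd.to_datetime(sub[ref_col])
    missing_ref = refs.isna()
    n_unresolved = sub.loc[missing_ref, cg.id_col].nunique()
    if n_unresolved:
        logger.info(
            "trajectory_table: %d participant(s) have no '%s' reference; "
            "their samples are un-highlighted",
            n_unresolved,
            ref_col,
        )
    lo = pd.to_timedelta(int(highlight_window.offset_lo), unit="D")
    hi = pd.to_timedelta(int(highlight_window.offset_hi), unit="D")
    highlighted = (
        refs.notna()
        & (sub[cg.date_col] >= refs + lo)
        & (sub[cg.date_col] <= refs + hi)
    )
    out = pd.DataFrame(
        {
            "participant": sub[cg.id_col].to_numpy(),
            "date": sub[cg.date_col].to_numpy(),
            "value": sub[value_col].to_numpy(),
            "highlighted": highlighted.to_numpy(),
        }
    )
    for c in facet_cols:
        out[c] = sub[c].to_numpy()
    out["sample_index"] = out.groupby("participant", sort=False).cumcount() + 1
    return out.reset_index(drop=True)
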