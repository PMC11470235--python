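"""Assembling chronograms from metadata and sparse experiment tables.

``assemble`` generates one row per participant per calendar day over an
inclusive span, broadcasts the per-participant metadata over those rows,
and left-joins each experiment table onto its {participant, date} keys.
``add_experiment`` joins a further experiment table later and commutes
with assembly: adding a table afterwards gives a cell-for-cell identical
result to including it from the start.

Every join is guarded: duplicate {participant, date} keys inside an
experiment table, duplicate participant ids in the metadata, unknown
participants, result-column name collisions and out-of-span observation
dates are all refused loudly rather than silently dropped (out-of-span
rows can be dropped on request, with a logged count).
"""

from __future__ import annotations

import logging
import re
import sqlite3
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from ._errors import (
    ChronogramError,
    ColumnCollisionError,
    DateParseError,
    DateSpanError,
    DuplicateKeyError,
    MissingColumnError,
    UnknownParticipantError,
)
from .core import ChronogramTable, as_day

__all__ = ["assemble", "add_experiment", "read_table"]

logger = logging.getLogger(__name__)

_ISO_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _coerce_day_column(series: pd.Series, context: str) -> pd.Series:
    """Coerce a column to timezone-free day-resolution datetimes.

    Accepts datetime64 columns, date/datetime objects, and strict
    ISO-8601 ``YYYY-MM-DD`` strings.  Anything else fails per-cell with
    the offending row indices listed — ambiguous dialects are never
    guessed here (see ``read_table`` for explicit formats).
    """
    if pd.api.types.is_datetime64_any_dtype(series):
        out = pd.to_datetime(series)
        if getattr(out.dt, "tz", None) is not None:
            out = out.dt.tz_localize(None)
        return out.dt.normalize()
    missing = series.isna()
    if missing.any():
        rows = list(series.index[missing][:10])
        raise DateParseError(
            f"{context}: missing date in rows {rows}",
            failures=[(r, None) for r in rows],
        )
    values = series.astype(object)
    is_str = values.map(lambda v: isinstance(v, str))
    parsed = pd.Series(pd.NaT, index=series.index, dtype="datetime64[ns]")
    if is_str.any():
        strs = values[is_str].str.strip()
        ok = strs.map(lambda v: bool(_ISO_RE.match(v)))
        good = pd.to_datetime(strs[ok], format="%Y-%m-%d", errors="coerce")
        parsed.loc[good.index] = good
    if (~is_str).any():
        nonstr = pd.to_datetime(values[~is_str], errors="coerce")
        parsed.loc[nonstr.index] = nonstr
    bad = parsed.isna()
    if bad.any():
        failures = [(i, series.loc[i]) for i in series.index[bad][:10]]
        raise DateParseError(
            f"{context}: unparseable calendar dates (expected YYYY-MM-DD) in rows "
            f"{[i for i, _ in failures]}: {[v for _, v in failures]}",
            failures=failures,
        )
    return parsed.dt.normalize()


def _named_experiments(experiments) -> list[tuple[str, pd.DataFrame]]:
    if experiments is None:
        return []
    if isinstance(experiments, Mapping):
        return [(str(k), v) for k, v in experiments.items()]
    out = []
    for i, exp in enumerate(experiments, start=1):
        name = getattr(exp, "name", None) or f"experiment_{i}"
        out.append((str(name), exp))
    return out


def assemble(
    start,
    end,
    metadata: pd.DataFrame,
    experiments: Union[Mapping[str, pd.DataFrame], Iterable[pd.DataFrame], None] = None,
    *,
    id_col: str = "participant_id",
    date_col: str = "date",
    drop_out_of_span: bool = False,
) -> ChronogramTable:
    """Build a dense chronogram over ``[start, end]`` (both inclusive).

    Parameters
    ----------
    start, end
        Inclusive span of calendar days; one row is generated per
        participant per day.
    metadata
        One row per participant; ``id_col`` must be unique and non-missing.
        All other columns are registered as metadata.
    experiments
        Mapping of name -> sparse experiment table (or an iterable, which
        gets positional names).  Each table must carry ``id_col`` and
        ``date_col`` plus one or more result columns.
    drop_out_of_span
        When True, observations dated outside the span are dropped with a
        logged count instead of aborting assembly.
    """
    start, end = as_day(start), as_day(end)
    if start > end:
        raise ChronogramError(f"start date {start.date()} is after end date {end.date()}")
    metadata = pd.DataFrame(metadata).copy()
    if id_col not in metadata.columns:
        raise MissingColumnError(f"id column '{id_col}' is absent from the metadata table")
    if date_col in metadata.columns:
        raise ChronogramError(
            f"metadata table must not contain the date column '{date_col}'"
        )
    if not len(metadata):
        raise ChronogramError("metadata table is empty: at least one participant required")
    if metadata[id_col].isna().any():
        raise ChronogramError("metadata contains missing participant ids")
    dup = metadata[id_col][metadata[id_col].duplicated()]
    if len(dup):
        raise DuplicateKeyError(
            f"duplicate participant_id in metadata: {dup.iloc[0]!r}"
        )

    dates = pd.date_range(start, end, freq="D")
    ids = metadata[id_col].to_numpy()
    grid = pd.DataFrame(
        {
            id_col: np.repeat(ids, len(dates)),
            date_col: np.tile(dates.to_numpy(), len(ids)),
        }
    )
    df = grid.merge(metadata, on=id_col, how="left", sort=False)
    cg = ChronogramTable(
        data=df.reset_index(drop=True),
        id_col=id_col,
        date_col=date_col,
        metadata_cols=[c for c in metadata.columns if c != id_col],
        date_span=(start, end),
    )
    for name, exp in _named_experiments(experiments):
        cg = add_experiment(cg, exp, name=name, drop_out_of_span=drop_out_of_span)
    return cg


def add_experiment(
    cg: ChronogramTable,
    exp: pd.DataFrame,
    *,
    name: str = "experiment",
    drop_out_of_span: bool = False,
) -> ChronogramTable:
    """Left-join a sparse experiment table onto an existing chronogram.

    Equivalent, cell for cell, to having passed the table to ``assemble``.
    """
    exp = pd.DataFrame(exp).copy()
    for col, what in ((cg.id_col, "id"), (cg.date_col, "date")):
        if col not in exp.columns:
            raise MissingColumnError(
                f"{what} column '{col}' is absent from experiment '{name}'"
            )
    value_cols = [c for c in exp.columns if c not in (cg.id_col, cg.date_col)]
    collisions = [c for c in value_cols if c in cg.data.columns]
    if collisions:
        raise ColumnCollisionError(
            f"column_collision: column(s) {collisions} from experiment "
            f"'{name}' already exist in the chronogram"
        )

    if len(exp):
        exp[cg.date_col] = _coerce_day_column(exp[cg.date_col], f"experiment '{name}'")
        dup_mask = exp.duplicated([cg.id_col, cg.date_col], keep="first")
        if dup_mask.any():
            pid, d = exp.loc[dup_mask.idxmax(), [cg.id_col, cg.date_col]]
            raise DuplicateKeyError(
                f"duplicate_key in experiment '{name}': {{{pid}, {d.date()}}}"
            )
        known = set(cg.participants)
        unknown = sorted({p for p in exp[cg.id_col] if p not in known}, key=str)
        if unknown:
            raise UnknownParticipantError(
                f"experiment '{name}' references participant(s) absent from "
                f"metadata: {unknown[:10]}"
            )
        if cg.date_span is not None:
            start, end = cg.date_span
            outside = (exp[cg.date_col] < start) | (exp[cg.date_col] > end)
            if outside.any():
                n_out = int(outside.sum())
                if drop_out_of_span:
                    logger.info(
                        "experiment '%s': dropped %d observation(s) outside %s..%s",
                        name,
                        n_out,
                        start.date(),
                        end.date(),
                    )
                    exp = exp.loc[~outside]
                else:
                    example = exp.loc[outside, cg.date_col].iloc[0]
                    raise DateSpanError(
                        f"experiment '{name}': {n_out} observation(s) dated outside "
                        f"{start.date()}..{end.date()} (e.g. {example.date()}); pass "
                        f"drop_out_of_span=True to drop them"
                    )
    else:
        # an empty table still contributes its (all-missing) result columns
        exp[cg.date_col] = pd.to_datetime(exp[cg.date_col])

    # canonical absent marker: object columns use NaN, never None
    for c in value_cols:
        if pd.api.types.is_object_dtype(exp[c]):
            exp[c] = exp[c].where(exp[c].notna(), np.nan)
    merged = cg.data.merge(exp, on=[cg.id_col, cg.date_col], how="left", sort=False)
    return cg.replace(data=merged.reset_index(drop=True))


def _parse_declared_dates(df, date_cols, date_format):
    fmt = date_format or "%Y-%m-%d"
    for c in date_cols:
        if c not in df.columns:
            raise MissingColumnError(f"declared date column '{c}' not found")
        s = df[c]
        if pd.api.types.is_datetime64_any_dtype(s):
            df[c] = pd.to_datetime(s).dt.normalize()
            continue
        notna = s.notna()
        parsed = pd.to_datetime(
            s[notna].astype(str).str.strip(), format=fmt, errors="coerce"
        )
        bad = parsed.isna()
        if bad.any():
            failures = [(int(i), s.loc[i]) for i in parsed.index[bad][:20]]
            raise DateParseError(
                f"column '{c}': {int(bad.sum())} cell(s) do not match date format "
                f"'{fmt}' (rows {[i for i, _ in failures]}); set date_format to the "
                f"table's dialect — ambiguous formats are never guessed",
                failures=failures,
            )
        out = pd.Series(pd.NaT, index=s.index, dtype="datetime64[ns]")
        out.loc[parsed.index] = parsed
        df[c] = out.dt.normalize()
    return df


def _autodetect_dates(df, skip):
    for c in df.columns:
        if c in skip or not (
            pd.api.types.is_object_dtype(df[c]) or pd.api.types.is_string_dtype(df[c])
        ):
            continue
        vals = df[c].dropna()
        if not len(vals):
            continue
        if vals.map(lambda v: isinstance(v, str) and bool(_ISO_RE.match(v.strip()))).all():
            parsed = pd.to_datetime(vals.str.strip(), format="%Y-%m-%d", errors="coerce")
            if parsed.notna().all():
                out = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns]")
                out.loc[parsed.index] = parsed
                df[c] = out
    return df


_NA_STRINGS = ["", "NA", "N/A", "NaN", "nan", "NULL", "null"]


def read_table(
    source,
    table_name: Optional[str] = None,
    *,
    id_col: Optional[str] = None,
    date_cols: Optional[list[str]] = None,
    date_format: Optional[str] = None,
) -> pd.DataFrame:
    """Read a metadata or experiment table from CSV or a SQLite database.

    ``source`` may be a ``.csv`` path, a SQLite file path (``.sqlite``,
    ``.sqlite3``, ``.db``) or a ``sqlite:///path`` URL; for SQL sources
    ``table_name`` selects the table.  Source-specific missing-value
    encodings ("", "NA", NULL) collapse to one canonical absent marker.

    Columns named in ``date_cols`` are parsed strictly with
    ``date_format`` (default ISO-8601 ``%Y-%m-%d``); any cell that fails
    is reported with its row index rather than silently coerced.  Other
    text columns whose every non-missing value is a full ISO date are
    parsed automatically.  ``id_col``, when given, is kept as an opaque
    string (so leading zeros survive).
    """
    src = str(source)
    is_sqlite = src.startswith("sqlite:///") or Path(src).suffix.lower() in {
        ".sqlite",
        ".sqlite3",
        ".db",
    }
    if is_sqlite:
        path = src[len("sqlite:///"):] if src.startswith("sqlite:///") else src
        if not Path(path).exists():
            raise FileNotFoundError(f"SQLite database not found: {path}")
        if table_name is None:
            raise ChronogramError("table_name is required for SQL sources")
        if not _IDENT_RE.match(table_name):
            raise ChronogramError(f"invalid SQL table name: {table_name!r}")
        with sqlite3.connect(path) as con:
            exists = con.execute(
                "SELECT name FROM sqlite_master WHERE type='table' AND name=?",
                (table_name,),
            ).fetchone()
            if exists is None:
                raise ChronogramError(
                    f"table '{table_name}' does not exist in {path}"
                )
            df = pd.read_sql_query(f'SELECT * FROM "{table_name}"', con)
        df = df.replace({s: np.nan for s in _NA_STRINGS if s})
        df = df.mask(df.map(lambda v: isinstance(v, str) and v == ""))
    else:
        if not Path(src).exists():
            raise FileNotFoundError(f"file not found: {src}")
        dtype = {id_col: str} if id_col else None
        df = pd.read_csv(
            src, keep_default_na=False, na_values=_NA_STRINGS, dtype=dtype
        )
    if id_col is not None:
        if id_col not in df.columns:
            raise MissingColumnError(f"id column '{id_col}' not found in {src}")
        df[id_col] = df[id_col].map(lambda v: v if pd.isna(v) else str(v))
    declared = list(date_cols or [])
    df = _parse_declared_dates(df, declared, date_format)
    df = _autodetect_dates(df, skip=set(declared) | ({id_col} if id_col else set()))
    return df
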