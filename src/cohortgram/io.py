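"""Lossless sparse serialization of chronograms.

A saved chronogram is a directory holding three plain-text parts, kept
deliberately inspectable and diff-able:

* ``manifest.json`` — format version, key column names, date span,
  column registries, per-column dtypes, provenance, and SHA-256
  checksums of the other parts;
* ``metadata.csv`` — one collapsed row per participant;
* ``observations.csv`` — only the {participant, date} rows that carry
  information: any non-missing experiment/annotation value, or a change
  point of a dense derived column (cumulative counts, history strings),
  which are forward-filled on load.

File size therefore grows with the number of observations and events,
not with participants x days.  ``load(save(cg))`` reproduces the source
chronogram cell-for-cell, attribute-for-attribute; annotation columns
are saved and restored verbatim, never recomputed, so loading can never
silently change analysis results after an algorithm update.

Saving is byte-deterministic: identical chronograms produce identical
containers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ChronogramError, IntegrityError, UnsupportedVersionError
from .core import ChronogramTable, as_day, collapse_metadata

__all__ = ["save_chronogram", "load_chronogram", "FORMAT"]

FORMAT = "cohortgram-v1"

_PARTS = ("metadata.csv", "observations.csv", "keys.csv")


def _dtype_code(series: pd.Series) -> str:
    dt = series.dtype
    if pd.api.types.is_datetime64_any_dtype(dt):
        return "date"
    if isinstance(dt, pd.Int64Dtype):
        return "Int64"
    if isinstance(dt, pd.BooleanDtype):
        return "boolean"
    if pd.api.types.is_bool_dtype(dt):
        return "bool"
    if pd.api.types.is_integer_dtype(dt):
        return "int64"
    if pd.api.types.is_float_dtype(dt):
        return "float64"
    return "str"


def _fmt_cell(v, code: str) -> str:
    if pd.isna(v):
        return ""
    if code == "date":
        return pd.Timestamp(v).strftime("%Y-%m-%d")
    if code in ("bool", "boolean"):
        return "True" if v else "False"
    if code in ("int64", "Int64"):
        return str(int(v))
    if code == "float64":
        return repr(float(v))
    return str(v)


def _frame_to_csv(df: pd.DataFrame, codes: dict[str, str], path: Path) -> None:
    out = pd.DataFrame(index=df.index)
    for c in df.columns:
        code = codes[c]
        out[c] = [_fmt_cell(v, code) for v in df[c]]
    out.to_csv(path, index=False, lineterminator="\n")


def _cast_column(s: pd.Series, code: str) -> pd.Series:
    # s arrives as raw strings with "" marking a missing cell
    blank = s.isna() | (s == "")
    if code == "date":
        return pd.to_datetime(s.where(~blank, None), format="%Y-%m-%d")
    if code == "float64":
        return pd.to_numeric(s.where(~blank, None)).astype("float64")
    if code == "int64":
        if blank.any():
            raise IntegrityError("int64 column has missing cells after reassembly")
        return pd.to_numeric(s).astype("int64")
    if code == "Int64":
        return pd.to_numeric(s.where(~blank, None)).astype("Int64")
    if code == "bool":
        if blank.any():
            raise IntegrityError("bool column has missing cells after reassembly")
        return s.map({"True": True, "False": False}).astype(bool)
    if code == "boolean":
        return s.where(~blank, None).map(
            {"True": True, "False": False, None: pd.NA}
        ).astype("boolean")
    return s.where(~blank, np.nan).astype(object)


def _encode_default(v, code: str):
    """JSON-native encoding of a dense-column default (None marks NA)."""
    if pd.isna(v):
        return None
    if code == "date":
        return pd.Timestamp(v).strftime("%Y-%m-%d")
    if code in ("bool", "boolean"):
        return bool(v)
    if code in ("int64", "Int64"):
        return int(v)
    if code == "float64":
        return float(v)
    return str(v)


def _decode_default(v, code: str):
    if v is None:
        return pd.NaT if code == "date" else np.nan
    if code == "date":
        return as_day(v)
    return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _na_neq(a: pd.Series, b: pd.Series) -> pd.Series:
    both_na = a.isna() & b.isna()
    eq = a == b
    eq = eq.fillna(False) if eq.dtype != bool else eq
    return ~(eq | both_na)


def save_chronogram(cg: ChronogramTable, path, *, overwrite: bool = True) -> Path:
    """Write a chronogram (or sub-cohort view) to a container directory."""
    p = Path(path)
    if p.exists() and not overwrite:
        raise ChronogramError(f"{p} already exists (pass overwrite=True)")
    p.mkdir(parents=True, exist_ok=True)

    df = cg.data.reset_index(drop=True)
    codes = {c: _dtype_code(df[c]) for c in df.columns}
    meta_cols = [c for c in cg.metadata_cols if c in df.columns]
    value_cols = [
        c for c in df.columns if c not in {cg.id_col, cg.date_col} and c not in meta_cols
    ]
    sparse_cols = [c for c in value_cols if c not in cg.dense_defaults]
    dense_cols = [c for c in value_cols if c in cg.dense_defaults]

    include = (
        df[sparse_cols].notna().any(axis=1)
        if sparse_cols
        else pd.Series(False, index=df.index)
    )
    if len(df):
        pid = df[cg.id_col].to_numpy()
        first_of_pid = np.r_[True, pid[1:] != pid[:-1]]
        for c in dense_cols:
            prev = df[c].shift(1)
            default = cg.dense_defaults[c]
            prev = prev.where(~first_of_pid, default)
            include |= _na_neq(df[c], prev)

    metadata_part = collapse_metadata(cg)
    meta_codes = {c: codes.get(c, _dtype_code(metadata_part[c])) for c in metadata_part.columns}
    _frame_to_csv(metadata_part, meta_codes, p / "metadata.csv")

    obs = df.loc[include, [cg.id_col, cg.date_col] + value_cols]
    _frame_to_csv(obs, codes, p / "observations.csv")

    parts = ["metadata.csv", "observations.csv"]
    if cg.is_view:
        keys = df[[cg.id_col, cg.date_col]]
        _frame_to_csv(keys, codes, p / "keys.csv")
        parts.append("keys.csv")
    else:
        (p / "keys.csv").unlink(missing_ok=True)

    span = None
    if cg.date_span is not None:
        span = [cg.date_span[0].strftime("%Y-%m-%d"), cg.date_span[1].strftime("%Y-%m-%d")]
    manifest = {
        "format": FORMAT,
        "id_col": cg.id_col,
        "date_col": cg.date_col,
        "date_span": span,
        "metadata_cols": meta_cols,
        "annotation_cols": [c for c in cg.annotation_cols if c in df.columns],
        "vaccine_dose_cols": cg.vaccine_dose_cols,
        "is_view": cg.is_view,
        "provenance": list(cg.provenance),
        "column_order": list(df.columns),
        "dtypes": codes,
        "dense_defaults": {
            c: _encode_default(v, codes[c])
            for c, v in cg.dense_defaults.items()
            if c in codes
        },
        "checksums": {name: _sha256(p / name) for name in parts},
    }
    (p / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return p


def _read_part(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])


def load_chronogram(path) -> ChronogramTable:
    """Reassemble a chronogram saved by :func:`save_chronogram`."""
    p = Path(path)
    manifest_path = p / "manifest.json"
    if not manifest_path.exists():
        raise ChronogramError(f"no manifest.json under {p}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != FORMAT:
        raise UnsupportedVersionError(
            f"unsupported container format {manifest.get('format')!r}; "
            f"this reader understands {FORMAT!r}"
        )
    for name, expect in manifest["checksums"].items():
        part = p / name
        if not part.exists():
            raise IntegrityError(f"missing container part: {name}")
        got = _sha256(part)
        if got != expect:
            raise IntegrityError(f"checksum mismatch for {name}")

    id_col = manifest["id_col"]
    date_col = manifest["date_col"]
    codes = manifest["dtypes"]
    span = manifest["date_span"]
    span_ts = None if span is None else (as_day(span[0]), as_day(span[1]))

    meta_raw = _read_part(p / "metadata.csv")
    meta = pd.DataFrame(index=meta_raw.index)
    for c in meta_raw.columns:
        meta[c] = _cast_column(meta_raw[c], codes.get(c, "str"))

    obs_raw = _read_part(p / "observations.csv")
    obs = pd.DataFrame(index=obs_raw.index)
    for c in obs_raw.columns:
        obs[c] = _cast_column(obs_raw[c], codes.get(c, "str"))

    if span_ts is not None and len(obs):
        if (obs[date_col] < span_ts[0]).any() or (obs[date_col] > span_ts[1]).any():
            raise IntegrityError(
                "observations dated outside the declared span: the manifest "
                "and the observation part disagree"
            )
    unknown = set(obs[id_col]) - set(meta[id_col]) if len(obs) else set()
    if unknown:
        raise IntegrityError(
            f"observations reference participants missing from metadata: "
            f"{sorted(unknown, key=str)[:5]}"
        )

    if manifest["is_view"]:
        keys_raw = _read_part(p / "keys.csv")
        rows = pd.DataFrame(
            {
                id_col: _cast_column(keys_raw[id_col], codes.get(id_col, "str")),
                date_col: _cast_column(keys_raw[date_col], "date"),
            }
        )
    else:
        if span_ts is None:
            raise IntegrityError("dense container without a date span")
        dates = pd.date_range(span_ts[0], span_ts[1], freq="D")
        ids = meta[id_col].to_numpy()
        rows = pd.DataFrame(
            {
                id_col: np.repeat(ids, len(dates)),
                date_col: np.tile(dates.to_numpy(), len(ids)),
            }
        )

    df = rows.merge(meta, on=id_col, how="left", sort=False)
    df = df.merge(obs, on=[id_col, date_col], how="left", sort=False)

    dense_defaults = {}
    for c, raw_default in manifest["dense_defaults"].items():
        code = codes.get(c, "str")
        default = _decode_default(raw_default, code)
        dense_defaults[c] = default
        if c in df.columns:
            filled = df.groupby(id_col, sort=False)[c].ffill()
            df[c] = filled.where(filled.notna(), default)

    for c in df.columns:
        df[c] = _cast_after_fill(df[c], codes.get(c, "str"))

    order = manifest["column_order"]
    df = df[[c for c in order if c in df.columns]]

    return ChronogramTable(
        data=df.reset_index(drop=True),
        id_col=id_col,
        date_col=date_col,
        metadata_cols=list(manifest["metadata_cols"]),
        annotation_cols=list(manifest["annotation_cols"]),
        date_span=span_ts,
        is_view=bool(manifest["is_view"]),
        provenance=list(manifest["provenance"]),
        vaccine_dose_cols=manifest.get("vaccine_dose_cols"),
        dense_defaults=dense_defaults,
    )


def _cast_after_fill(s: pd.Series, code: str) -> pd.Series:
    """Final dtype pass after grid expansion re-introduced NaN gaps."""
    if code == "date":
        return pd.to_datetime(s)
    if code == "float64":
        return s.astype("float64")
    if code == "int64":
        return s.astype("int64")
    if code == "Int64":
        return s.astype("Int64")
    if code == "bool":
        return s.astype(bool)
    if code == "boolean":
        return s.astype("boolean")
    return s.astype(object)
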