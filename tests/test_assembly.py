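"""Assembly: grid generation, guarded joins, table reading."""

import sqlite3

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cohortgram as cgm


def test_grid_without_experiments():
    metadata = pd.DataFrame({"participant_id": ["A", "B"], "g": [1, 2]})
    cg = cgm.assemble("2021-01-01", "2021-01-03", metadata)
    assert len(cg.data) == 6
    assert cg.experiment_cols == []
    assert cgm.validate(cg).ok
    assert cg.date_span == (cgm.as_day("2021-01-01"), cgm.as_day("2021-01-03"))


def test_single_observation_lands_on_its_day():
    metadata = pd.DataFrame({"participant_id": ["P1", "P2"]})
    serology = pd.DataFrame(
        {"participant_id": ["P1"], "date": ["2021-01-02"], "titer": [100.0]}
    )
    cg = cgm.assemble(
        "2021-01-01", "2021-01-03", metadata, {"serology": serology}
    )
    hits = cg.data[cg.data["titer"].notna()]
    assert len(hits) == 1
    assert hits.iloc[0]["participant_id"] == "P1"
    assert hits.iloc[0]["date"] == cgm.as_day("2021-01-02")


def test_duplicate_experiment_key_refused_with_table_and_key_named():
    metadata = pd.DataFrame({"participant_id": ["P1"]})
    serology = pd.DataFrame(
        {
            "participant_id": ["P1", "P1"],
            "date": ["2021-01-02", "2021-01-02"],
            "titer": [1.0, 2.0],
        }
    )
    with pytest.raises(
        cgm.DuplicateKeyError, match=r"duplicate_key in experiment 'serology'.*P1.*2021-01-02"
    ):
        cgm.assemble("2021-01-01", "2021-01-03", metadata, {"serology": serology})


def test_duplicate_metadata_participant_refused():
    metadata = pd.DataFrame({"participant_id": ["P1", "P1"]})
    with pytest.raises(cgm.DuplicateKeyError, match="P1"):
        cgm.assemble("2021-01-01", "2021-01-02", metadata)


def test_unknown_experiment_participant_refused():
    metadata = pd.DataFrame({"participant_id": ["P1"]})
    exp = pd.DataFrame({"participant_id": ["P9"], "date": ["2021-01-01"], "x": [1]})
    with pytest.raises(cgm.UnknownParticipantError, match="P9"):
        cgm.assemble("2021-01-01", "2021-01-02", metadata, {"e": exp})


def test_out_of_span_observation_refused_by_default_dropped_on_request(caplog):
    metadata = pd.DataFrame({"participant_id": ["P1"]})
    exp = pd.DataFrame({"participant_id": ["P1"], "date": ["2021-02-01"], "x": [1]})
    with pytest.raises(cgm.DateSpanError, match="2021-02-01"):
        cgm.assemble("2021-01-01", "2021-01-05", metadata, {"e": exp})
    with caplog.at_level("INFO"):
        cg = cgm.assemble(
            "2021-01-01", "2021-01-05", metadata, {"e": exp}, drop_out_of_span=True
        )
    assert cg.data["x"].isna().all()
    assert any("dropped 1" in m for m in caplog.messages)


def test_column_collision_refused():
    metadata = pd.DataFrame({"participant_id": ["P1"]})
    a = pd.DataFrame({"participant_id": ["P1"], "date": ["2021-01-01"], "x": [1]})
    b = pd.DataFrame({"participant_id": ["P1"], "date": ["2021-01-02"], "x": [2]})
    with pytest.raises(cgm.ColumnCollisionError, match="column_collision.*'x'"):
        cgm.assemble("2021-01-01", "2021-01-03", metadata, {"a": a, "b": b})


def test_add_experiment_commutes_with_assembly(tiny_tables):
    metadata, serology, swab = tiny_tables
    both = cgm.assemble(
        "2021-01-01", "2021-01-10", metadata, {"serology": serology, "swab": swab}
    )
    late = cgm.add_experiment(
        cgm.assemble("2021-01-01", "2021-01-10", metadata, {"serology": serology}),
        swab,
        name="swab",
    )
    assert cgm.chronograms_equal(both, late)


def test_adding_empty_experiment_contributes_all_missing_column(tiny_cg):
    empty = pd.DataFrame({"participant_id": [], "date": [], "lft": []})
    cg = cgm.add_experiment(tiny_cg, empty, name="lft")
    assert "lft" in cg.data.columns
    assert cg.data["lft"].isna().all()
    assert cgm.validate(cg).ok


def test_cell_values_insensitive_to_input_row_order(tiny_tables):
    metadata, serology, swab = tiny_tables
    ref = cgm.assemble("2021-01-01", "2021-01-10", metadata, {"s": serology})
    shuffled = cgm.assemble(
        "2021-01-01",
        "2021-01-10",
        metadata.sample(frac=1, random_state=1),
        {"s": serology.sample(frac=1, random_state=2)},
    )
    key = ["participant_id", "date"]
    a = ref.data.sort_values(key).reset_index(drop=True)
    b = shuffled.data.sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=1, max_value=8),
    n_days=st.integers(min_value=1, max_value=40),
)
def test_row_count_is_participants_times_days(n, n_days):
    metadata = pd.DataFrame({"participant_id": [f"P{i}" for i in range(n)]})
    start = cgm.as_day("2021-03-01")
    cg = cgm.assemble(start, start + pd.Timedelta(days=n_days - 1), metadata)
    assert len(cg.data) == n * n_days
    assert cgm.validate(cg).ok


# -- read_table ---------------------------------------------------------------


def test_read_csv_parses_iso_dates_and_keeps_opaque_ids(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text(
        "participant_id,date,result\n007,2021-03-07,positive\n008,2021-03-08,\n"
    )
    df = cgm.read_table(f, id_col="participant_id", date_cols=["date"])
    assert list(df["participant_id"]) == ["007", "008"]  # leading zeros survive
    assert df.loc[0, "date"] == cgm.as_day("2021-03-07")
    assert pd.isna(df.loc[1, "result"])


def test_ambiguous_date_dialect_is_a_per_cell_error(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("participant_id,date\nP1,07/03/2021\n")
    with pytest.raises(cgm.DateParseError) as exc:
        cgm.read_table(f, date_cols=["date"])
    assert exc.value.failures == [(0, "07/03/2021")]
    # an explicit dialect resolves it
    df = cgm.read_table(f, date_cols=["date"], date_format="%d/%m/%Y")
    assert df.loc[0, "date"] == cgm.as_day("2021-03-07")


def test_iso_looking_text_columns_are_autodetected(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("participant_id,dose_1_date,label\nP1,2021-01-05,2021-01\n")
    df = cgm.read_table(f)
    assert pd.api.types.is_datetime64_any_dtype(df["dose_1_date"])
    assert df.loc[0, "label"] == "2021-01"  # month strings stay text


def test_read_sqlite_table(tmp_path):
    db = tmp_path / "study.sqlite"
    with sqlite3.connect(db) as con:
        pd.DataFrame(
            {"participant_id": ["P1", "P2"], "dose_1_date": ["2021-01-05", "2021-02-01"]}
        ).to_sql("metadata", con, index=False)
    df = cgm.read_table(db, "metadata", id_col="participant_id")
    assert len(df) == 2
    assert pd.api.types.is_datetime64_any_dtype(df["dose_1_date"])
    with pytest.raises(cgm.ChronogramError, match="does not exist"):
        cgm.read_table(db, "nope")
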