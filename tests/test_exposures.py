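"""Cumulative exposure counts and antigenic history strings."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cohortgram as cgm


def _cg_with_doses(dose1, dose2, span=("2021-01-01", "2021-04-01"), **experiments):
    metadata = pd.DataFrame(
        {
            "participant_id": ["P1"],
            "dose_1_date": pd.to_datetime([dose1]),
            "dose_2_date": pd.to_datetime([dose2]),
        }
    )
    exps = {
        col: pd.DataFrame(
            {
                "participant_id": ["P1"] * len(obs),
                "date": pd.to_datetime(list(obs)),
                col: list(obs.values()),
            }
        )
        for col, obs in experiments.items()
    }
    return cgm.assemble(span[0], span[1], metadata, exps)


def test_vaccines_count_steps_on_each_dose_date():
    cg = _cg_with_doses("2021-01-01", "2021-03-01")
    cg = cgm.vaccines_count(cg, ["dose_1_date", "dose_2_date"])
    s = cg.data.set_index("date")["vaccines_count"]
    assert s["2021-01-01"] == 1  # increments on the dose day itself
    assert s["2021-02-28"] == 1
    assert s["2021-03-01"] == 2
    assert s["2021-04-01"] == 2


def test_participant_without_doses_counts_zero():
    metadata = pd.DataFrame(
        {"participant_id": ["P1"], "dose_1_date": pd.to_datetime([pd.NaT])}
    )
    cg = cgm.assemble("2021-01-01", "2021-01-10", metadata)
    cg = cgm.vaccines_count(cg, ["dose_1_date"])
    assert (cg.data["vaccines_count"] == 0).all()


def test_misordered_dose_dates_are_refused():
    cg = _cg_with_doses("2021-03-01", "2021-01-01")
    with pytest.raises(cgm.DoseOrderError, match="P1"):
        cgm.vaccines_count(cg, ["dose_1_date", "dose_2_date"])


def test_exposures_is_rowwise_sum_of_vaccines_and_episodes(small_cg):
    df = small_cg.data
    assert (df["exposures_count"] == df["vaccines_count"] + df["episodes_count"]).all()


def test_exposures_requires_both_counts(tiny_cg):
    with pytest.raises(cgm.AnnotationOrderError):
        cgm.exposures_count(tiny_cg)


def _history_cg():
    cg = _cg_with_doses(
        "2021-01-01",
        "2021-03-01",
        sequencing={"2021-02-11": "Delta"},
        symptom={"2021-02-10": "Y"},
    )
    cg = cgm.episodes_find(
        cg, cgm.EvidenceSpec({"symptom": ["Y"], "sequencing": ["Delta"]}), max_gap=7
    )
    cg = cgm.episodes_fill(cg, ["sequencing"])
    cg = cgm.episodes_count(cg)
    cg = cgm.vaccines_count(cg, ["dose_1_date", "dose_2_date"])
    cg = cgm.exposures_count(cg)
    return cgm.antigenic_history(cg, "sequencing_filled")


def test_history_interleaves_vaccines_and_labelled_infections():
    cg = _history_cg()
    h = cg.data.set_index("date")["antigenic_history"]
    assert h["2021-03-15"] == "V1:I1[Delta]:V2"
    assert h["2021-02-20"] == "V1:I1[Delta]"
    assert h["2021-01-15"] == "V1"


def test_history_is_empty_before_any_exposure():
    cg = _history_cg()
    # span starts on dose-1 day, so shift dose 1 later to get a pre-exposure day
    cg2 = _cg_with_doses("2021-01-05", "2021-03-01")
    cg2 = cgm.episodes_find(cg2, cgm.EvidenceSpec({"dose_1_date": ["never"]}))
    cg2 = cgm.episodes_count(cg2)
    cg2 = cgm.vaccines_count(cg2, ["dose_1_date", "dose_2_date"])
    cg2 = cgm.exposures_count(cg2)
    cg2 = cgm.antigenic_history(cg2)
    h = cg2.data.set_index("date")["antigenic_history"]
    assert h["2021-01-04"] == ""
    assert h["2021-01-05"] == "V1"


def test_history_code_count_equals_exposures_count(small_cg):
    df = small_cg.data
    n_codes = df["antigenic_history"].map(lambda h: len(cgm.parse_history(h)))
    assert (n_codes == df["exposures_count"]).all()


def test_history_is_prefix_monotone_per_participant(small_cg):
    for _, sub in small_cg.data.groupby("participant_id", sort=False):
        hs = sub.sort_values("date")["antigenic_history"].tolist()
        for a, b in zip(hs, hs[1:]):
            assert b == a or b.startswith(a + ":") or a == ""


def test_history_requires_prerequisites(tiny_cg):
    with pytest.raises(cgm.AnnotationOrderError):
        cgm.antigenic_history(tiny_cg)


def test_parse_history_round_trips():
    events = cgm.parse_history("V1:I1[Delta]:V2:I2")
    assert events == [
        {"kind": "vaccine", "ordinal": 1, "label": None},
        {"kind": "infection", "ordinal": 1, "label": "Delta"},
        {"kind": "vaccine", "ordinal": 2, "label": None},
        {"kind": "infection", "ordinal": 2, "label": None},
    ]
    assert cgm.parse_history("") == []
    with pytest.raises(ValueError, match="malformed"):
        cgm.parse_history("X9")


def test_seroconversion_only_infections_optional_in_history():
    cg = _cg_with_doses(
        "2021-01-01",
        "2021-03-01",
        anti_n={"2021-01-10": "negative", "2021-02-20": "positive"},
    )
    cg = cgm.episodes_find(cg, cgm.EvidenceSpec({"anti_n": ["never-matches"]}))
    cg = cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))
    cg = cgm.episodes_count(cg)
    cg = cgm.vaccines_count(cg, ["dose_1_date", "dose_2_date"])
    cg = cgm.exposures_count(cg)
    without = cgm.antigenic_history(cg)
    assert without.data.set_index("date")["antigenic_history"]["2021-03-01"] == "V1:V2"
    with_sero = cgm.antigenic_history(cg, include_seroconversions=True)
    h = with_sero.data.set_index("date")["antigenic_history"]
    # the sero-detected infection is dated at the first positive draw
    assert h["2021-02-20"] == "V1:I1"
    assert h["2021-02-19"] == "V1"


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    dose_offsets=st.lists(
        st.integers(min_value=0, max_value=80), min_size=0, max_size=3, unique=True
    ),
    evidence_offset=st.one_of(st.none(), st.integers(min_value=0, max_value=89)),
)
def test_count_and_history_monotonicity_on_random_events(dose_offsets, evidence_offset):
    start = cgm.as_day("2021-01-01")
    doses = sorted(dose_offsets)
    meta = {"participant_id": ["P1"]}
    dose_cols = []
    for k, o in enumerate(doses, start=1):
        col = f"dose_{k}_date"
        meta[col] = pd.to_datetime([start + pd.Timedelta(days=o)])
        dose_cols.append(col)
    exps = {}
    if evidence_offset is not None:
        exps["symptom"] = pd.DataFrame(
            {
                "participant_id": ["P1"],
                "date": [start + pd.Timedelta(days=evidence_offset)],
                "symptom": ["Y"],
            }
        )
    cg = cgm.assemble(start, start + pd.Timedelta(days=89), pd.DataFrame(meta), exps)
    if "symptom" not in cg.data.columns:
        cg.data["symptom"] = pd.Series([None] * len(cg.data), dtype=object)
    cg = cgm.episodes_find(cg, cgm.EvidenceSpec({"symptom": ["Y"]}))
    cg = cgm.episodes_count(cg)
    if dose_cols:
        cg = cgm.vaccines_count(cg, dose_cols)
    else:
        cg.data["vaccines_count"] = 0
        cg = cg.replace(
            data=cg.data,
            annotation_cols=cg.annotation_cols + ["vaccines_count"],
            vaccine_dose_cols=[],
        )
    cg = cgm.exposures_count(cg)
    cg = cgm.antigenic_history(cg)
    df = cg.data
    for col in ("vaccines_count", "episodes_count", "exposures_count"):
        assert (df[col].diff().fillna(0) >= 0).all()
    assert df["exposures_count"].iloc[-1] == len(doses) + (
        1 if evidence_offset is not None else 0
    )
    n_codes = df["antigenic_history"].map(lambda h: len(cgm.parse_history(h)))
    assert (n_codes == df["exposures_count"]).all()
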