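"""Episode detection, seroconversion windows, filling and counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cohortgram as cgm
from helpers import episode_oracle, sero_oracle


def _one_person_cg(start, end, **experiments):
    """Single-participant chronogram with sparse experiment columns.

    Each keyword maps a column name to a {date: value} dict.
    """
    metadata = pd.DataFrame({"participant_id": ["P1"]})
    exps = {}
    for col, obs in experiments.items():
        exps[col] = pd.DataFrame(
            {
                "participant_id": ["P1"] * len(obs),
                "date": pd.to_datetime(list(obs)),
                col: list(obs.values()),
            }
        )
    return cgm.assemble(start, end, metadata, exps)


def test_nearby_evidence_days_merge_into_one_episode():
    cg = _one_person_cg(
        "2021-01-01",
        "2021-01-31",
        symptom={"2021-01-05": "Y"},
        pcr={"2021-01-07": "positive"},
    )
    cg = cgm.episodes_find(
        cg, cgm.EvidenceSpec({"symptom": ["Y"], "pcr": ["positive"]}), max_gap=7
    )
    tab = cgm.episodes_table(cg)
    assert len(tab) == 1
    assert tab.loc[0, "episode_number"] == 1
    assert tab.loc[0, "start_date"] == cgm.as_day("2021-01-05")
    assert tab.loc[0, "end_date"] == cgm.as_day("2021-01-07")
    # every day inside the span carries the number, outside is absent
    inside = cg.data[
        cg.data["date"].between("2021-01-05", "2021-01-07")
    ]["episode_number"]
    assert (inside == 1).all()
    outside = cg.data[~cg.data["date"].between("2021-01-05", "2021-01-07")]
    assert outside["episode_number"].isna().all()
    assert tab.loc[0, "evidence_summary"] == "pcr:1;symptom:1"


def test_distant_evidence_days_split_into_numbered_episodes():
    cg = _one_person_cg(
        "2021-01-01",
        "2021-03-31",
        symptom={"2021-01-05": "Y", "2021-03-20": "Y"},
    )
    cg = cgm.episodes_find(cg, cgm.EvidenceSpec({"symptom": ["Y"]}), max_gap=7)
    tab = cgm.episodes_table(cg)
    assert list(tab["episode_number"]) == [1, 2]
    assert list(tab["start_date"]) == [cgm.as_day("2021-01-05"), cgm.as_day("2021-03-20")]


def test_no_evidence_days_yields_no_episodes():
    cg = _one_person_cg("2021-01-01", "2021-01-10", symptom={"2021-01-05": "N"})
    cg = cgm.episodes_find(cg, cgm.EvidenceSpec({"symptom": ["Y"]}))
    assert cg.data["episode_number"].isna().all()
    assert len(cgm.episodes_table(cg)) == 0


def test_matching_is_trimmed_and_case_folded():
    cg = _one_person_cg("2021-01-01", "2021-01-05", pcr={"2021-01-02": "  Positive "})
    cg = cgm.episodes_find(cg, cgm.EvidenceSpec({"pcr": ["positive"]}))
    assert cg.data["episode_number"].notna().sum() == 1


def test_rerun_refused_without_overwrite(tiny_cg):
    cg = cgm.episodes_find(tiny_cg, cgm.EvidenceSpec({"pcr": ["positive"]}))
    with pytest.raises(cgm.AnnotationStateError):
        cgm.episodes_find(cg, cgm.EvidenceSpec({"pcr": ["positive"]}))
    again = cgm.episodes_find(
        cg, cgm.EvidenceSpec({"pcr": ["positive"]}), overwrite=True
    )
    assert cgm.chronograms_equal(cg, again)  # idempotent under overwrite


def test_missing_scan_column_is_an_error(tiny_cg):
    with pytest.raises(cgm.MissingColumnError, match="nope"):
        cgm.episodes_find(tiny_cg, cgm.EvidenceSpec({"nope": ["Y"]}))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    offsets=st.sets(st.integers(min_value=0, max_value=59), max_size=20),
    max_gap=st.integers(min_value=0, max_value=30),
)
def test_episode_merging_matches_bruteforce_oracle(offsets, max_gap):
    start = cgm.as_day("2021-01-01")
    days = {start + pd.Timedelta(days=o): "Y" for o in offsets}
    cg = _one_person_cg(start, start + pd.Timedelta(days=59), symptom=days)
    cg = cgm.episodes_find(cg, cgm.EvidenceSpec({"symptom": ["Y"]}), max_gap=max_gap)
    tab = cgm.episodes_table(cg)
    expected = episode_oracle(days, max_gap)
    assert len(tab) == len(expected)
    got = list(zip(tab["start_date"], tab["end_date"]))
    assert got == expected
    # episodes are disjoint and separated by more than max_gap
    for (s0, e0), (s1, e1) in zip(got, got[1:]):
        assert (s1 - e0).days > max_gap


def test_episode_numbering_invariant_under_scan_col_order():
    kw = dict(
        symptom={"2021-01-05": "Y"},
        pcr={"2021-01-07": "positive", "2021-02-20": "positive"},
    )
    cg = _one_person_cg("2021-01-01", "2021-02-28", **kw)
    a = cgm.episodes_find(cg, cgm.EvidenceSpec({"symptom": ["Y"], "pcr": ["positive"]}))
    b = cgm.episodes_find(cg, cgm.EvidenceSpec({"pcr": ["positive"], "symptom": ["Y"]}))
    assert cgm.chronograms_equal(a, b)


# -- seroconversion -----------------------------------------------------------


def test_negative_to_positive_transition_creates_half_open_window():
    cg = _one_person_cg(
        "2021-01-15",
        "2021-05-15",
        anti_n={"2021-02-01": "negative", "2021-05-01": "positive"},
    )
    cg = cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))
    rows = cg.data[cg.data["sero_episode_number"].notna()]
    # window is (Feb 1, May 1]: the last-negative day itself is outside
    assert rows["date"].min() == cgm.as_day("2021-02-02")
    assert rows["date"].max() == cgm.as_day("2021-05-01")
    assert (rows["sero_window_start"] == cgm.as_day("2021-02-01")).all()
    assert (rows["sero_window_end"] == cgm.as_day("2021-05-01")).all()
    assert not cg.data["baseline_seropositive"].any()


def test_always_positive_marker_is_baseline_positive_not_seroconversion():
    cg = _one_person_cg(
        "2021-01-01",
        "2021-06-01",
        anti_n={"2021-02-01": "positive", "2021-05-01": "positive"},
    )
    cg = cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))
    assert cg.data["baseline_seropositive"].all()
    assert cg.data["sero_episode_number"].isna().all()


def test_window_anchors_at_the_transition_pair_not_the_sequence_ends():
    cg = _one_person_cg(
        "2021-01-01",
        "2021-08-01",
        anti_n={
            "2021-01-10": "negative",
            "2021-03-10": "negative",
            "2021-05-10": "positive",
            "2021-07-10": "positive",
        },
    )
    cg = cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))
    rows = cg.data[cg.data["sero_episode_number"] == 1]
    assert rows["sero_window_start"].iloc[0] == cgm.as_day("2021-03-10")
    assert rows["sero_window_end"].iloc[0] == cgm.as_day("2021-05-10")
    assert cg.data["sero_episode_number"].max() == 1


def test_multiple_seroconversions_and_reversion_flag():
    cg = _one_person_cg(
        "2021-01-01",
        "2021-12-01",
        anti_n={
            "2021-01-10": "negative",
            "2021-03-10": "positive",
            "2021-06-10": "negative",
            "2021-09-10": "positive",
        },
    )
    cg = cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))
    assert cg.data["sero_episode_number"].max() == 2
    assert cg.data["sero_reversion"].all()


def test_unrecognized_marker_value_is_an_error():
    cg = _one_person_cg("2021-01-01", "2021-01-10", anti_n={"2021-01-05": "equivocal"})
    with pytest.raises(cgm.UnknownMarkerValueError, match="equivocal.*P1"):
        cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    states=st.lists(
        st.sampled_from([None, "negative", "positive"]), min_size=0, max_size=10
    )
)
def test_seroconversion_matches_pairwise_scan_oracle(states):
    start = cgm.as_day("2021-01-01")
    obs = {
        start + pd.Timedelta(days=10 * i): s
        for i, s in enumerate(states)
        if s is not None
    }
    cg = _one_person_cg(start, start + pd.Timedelta(days=99), anti_n=obs)
    cg = cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))
    baseline, intervals, reversion = sero_oracle(
        [(d, v == "positive") for d, v in obs.items()]
    )
    n_found = (
        0
        if cg.data["sero_episode_number"].isna().all()
        else int(cg.data["sero_episode_number"].max())
    )
    assert n_found == len(intervals)
    assert cg.data["baseline_seropositive"].all() == baseline or not baseline
    assert bool(cg.data["baseline_seropositive"].any()) == baseline
    assert bool(cg.data["sero_reversion"].any()) == reversion
    st_tab = cgm.seroconversions_table(cg)
    got = list(zip(st_tab["window_start"], st_tab["window_end"]))
    assert got == intervals


# -- fill & count -------------------------------------------------------------


def _episode_cg(**extra):
    cg = _one_person_cg(
        "2021-01-01",
        "2021-01-31",
        symptom={"2021-01-05": "Y", "2021-01-09": "Y"},
        **extra,
    )
    return cgm.episodes_find(cg, cgm.EvidenceSpec({"symptom": ["Y"]}), max_gap=7)


def test_fill_broadcasts_single_value_over_whole_episode():
    cg = _episode_cg(sequencing={"2021-01-06": "Delta"})
    cg = cgm.episodes_fill(cg, ["sequencing"])
    ep = cg.data[cg.data["episode_number"].notna()]
    assert (ep["sequencing_filled"] == "Delta").all()
    assert len(ep) == 5  # Jan 5..9
    assert cg.data.loc[cg.data["episode_number"].isna(), "sequencing_filled"].isna().all()


def test_fill_conflict_errors_by_default_and_takes_earliest_on_request():
    cg = _episode_cg(sequencing={"2021-01-06": "Delta", "2021-01-08": "Alpha"})
    with pytest.raises(cgm.FillConflictError, match="P1.*Delta.*Alpha"):
        cgm.episodes_fill(cg, ["sequencing"])
    cg = cgm.episodes_fill(cg, ["sequencing"], policy="first_nonmissing")
    ep = cg.data[cg.data["episode_number"].notna()]
    assert (ep["sequencing_filled"] == "Delta").all()


def test_fill_requires_episodes_first(tiny_cg):
    with pytest.raises(cgm.AnnotationOrderError):
        cgm.episodes_fill(tiny_cg, ["titer"])


def test_episode_count_steps_on_the_start_date():
    cg = cgm.episodes_count(_episode_cg())
    before = cg.data[cg.data["date"] < "2021-01-05"]["episodes_count"]
    after = cg.data[cg.data["date"] >= "2021-01-05"]["episodes_count"]
    assert (before == 0).all()
    assert (after == 1).all()


def test_episode_count_requires_find_first(tiny_cg):
    with pytest.raises(cgm.AnnotationOrderError, match="order"):
        cgm.episodes_count(tiny_cg)
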