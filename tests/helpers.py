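"""Shared helpers: independent oracles and the standard annotation pipeline.

The oracles here are deliberately naive re-statements of the definitions
(sort-and-split interval merging, consecutive-pair seroconversion scan)
so they stay independent of the library code paths they check.
"""

from __future__ import annotations

import pandas as pd

import cohortgram as cgm


def episode_oracle(evidence_days, max_gap):
    """Brute-force interval merging: sort evidence days, split at gaps > max_gap.

    ``evidence_days`` is any iterable of day numbers or timestamps;
    returns a list of (start, end) spans.
    """
    days = sorted(set(evidence_days))
    spans = []
    for d in days:
        if spans and _day_diff(d, spans[-1][1]) <= max_gap:
            spans[-1][1] = d
        else:
            spans.append([d, d])
    return [(s, e) for s, e in spans]


def _day_diff(a, b):
    d = a - b
    return d.days if hasattr(d, "days") else d


def sero_oracle(measurements):
    """Consecutive-pair scan over (date, state) measurements.

    ``state`` is True (positive) / False (negative); missing days are
    simply not in the list.  Returns (baseline_positive, intervals,
    any_reversion) where intervals are (last_negative, first_positive]
    pairs.
    """
    if not measurements:
        return False, [], False
    measurements = sorted(measurements, key=lambda t: t[0])
    baseline = bool(measurements[0][1])
    intervals = []
    reversion = False
    for (d0, s0), (d1, s1) in zip(measurements, measurements[1:]):
        if s0 and not s1:
            reversion = True
        if (not s0) and s1:
            intervals.append((d0, d1))
    return baseline, intervals, reversion


def standard_evidence_spec(design=None):
    """The evidence spec that recovers the synthetic generator's truth."""
    design = design or cgm.CohortDesign()
    return cgm.EvidenceSpec(
        scan={
            "symptom": ["Y"],
            "pcr_result": ["positive"],
            "sequencing": [design.early_variant, design.late_variant],
        }
    )


def assemble_cohort(cohort, experiments=None):
    return cgm.assemble(
        cohort.design.study_start,
        cohort.design.study_end,
        cohort.metadata,
        cohort.experiments if experiments is None else experiments,
    )


def full_annotate(cg, design=None, max_gap=7):
    """Episode finding through antigenic history, in prerequisite order."""
    cg = cgm.episodes_find(cg, standard_evidence_spec(design), max_gap=max_gap)
    cg = cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))
    cg = cgm.episodes_fill(cg, ["sequencing"])
    cg = cgm.episodes_count(cg)
    cg = cgm.vaccines_count(cg, ["dose_1_date", "dose_2_date"])
    cg = cgm.exposures_count(cg)
    cg = cgm.antigenic_history(cg, "sequencing_filled")
    return cg


def end_of_study_rows(cg) -> pd.DataFrame:
    """Last row of each participant, indexed by participant id."""
    return (
        cg.data.groupby(cg.id_col, sort=False).tail(1).set_index(cg.id_col)
    )
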