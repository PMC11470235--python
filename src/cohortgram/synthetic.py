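"""Synthetic vaccine-cohort generator with known ground truth.

Emulates the shape of a REDCap/LIMS export from a two-dose SARS-CoV-2
vaccine study in healthcare workers: participants split into long
(10-12 week) versus short (3-4 week) dose-interval groups, with and
without infection prior to dose 1; anti-Spike IgG trajectories sampled
at scheduled venepuncture visits; anti-nucleocapsid IgG status that is
positive throughout for the previously infected and seroconverts
mid-study in participants infected during follow-up; and swab/symptom
evidence rows scattered 0-3 days apart around each true infection date,
so that episode detection genuinely has to merge them.

Every participant's ground truth (group labels, dose dates, infection
episode, seroconversion visit, expected end-of-study antigenic history)
is emitted alongside the tables, enabling exact pipeline-recovery
tests.  Generation is fully deterministic given the design's seed.

Dose-1 dates follow the public-release convention of month-resolution
dates: each participant carries a ``YYYY-MM`` first-dose month plus an
interval in days, and :func:`perturb_dates` draws the day-of-month
uniformly from 1..28 and recomputes every downstream date from the
resulting first-dose date plus the stored intervals (so intervals are
preserved exactly).
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._errors import DesignError, MissingColumnError
from .core import as_day

__all__ = ["CohortDesign", "SyntheticCohort", "generate_cohort", "perturb_dates", "demo_design"]


@dataclass(frozen=True)
class CohortDesign:
    """Study-design parameters for the synthetic cohort.

    Defaults describe a cohort of 200 healthcare workers enrolled over
    early 2021, half on the long (70-84 day) and half on the short
    (21-28 day) dose interval, a quarter of each arm previously
    infected, with four venepuncture visits per participant and a 10%
    mid-study infection risk.  Peak anti-S geometric means embed a
    long>short effect in the previously uninfected stratum only; the
    prior-infected stratum's effect is zero by design.
    """

    n_participants: int = 200
    long_fraction: float = 0.5
    prior_infected_fraction: float = 0.25
    study_start: str = "2020-12-01"
    study_end: str = "2021-09-30"
    dose1_months: tuple[str, ...] = ("2021-01", "2021-02", "2021-03")
    long_interval_days: tuple[int, int] = (70, 84)   # 10-12 weeks
    short_interval_days: tuple[int, int] = (21, 28)  # 3-4 weeks
    # visit offsets in days; first two relative to dose 1, last two to dose 2
    baseline_visit_offset: tuple[int, int] = (-14, -7)
    postdose1_visit_offset: tuple[int, int] = (20, 27)
    peak_visit_offset: tuple[int, int] = (28, 35)
    late_visit_offset: tuple[int, int] = (70, 84)
    # anti-S IgG geometric means (arbitrary BAU/ml-like units)
    baseline_titer_gm: tuple[float, float] = (5.0, 150.0)      # (uninfected, prior-infected)
    postdose1_titer_gm: tuple[float, float] = (100.0, 2000.0)  # (uninfected, prior-infected)
    peak_titer_gm_long_uninfected: float = 2000.0
    peak_titer_gm_short_uninfected: float = 800.0
    peak_titer_gm_long_infected: float = 5000.0
    peak_titer_gm_short_infected: float = 5000.0
    late_titer_decay: float = 0.5
    titer_log10_sd: float = 0.15
    infection_prob: float = 0.10
    infection_offset_days: tuple[int, int] = (21, 140)  # relative to dose 1
    evidence_scatter_days: int = 3
    seroconversion_lag_days: int = 14
    variant_switch_date: str = "2021-06-01"
    early_variant: str = "Alpha"
    late_variant: str = "Delta"
    negative_test_prob: float = 0.2
    seed: int = 0

    def check(self) -> None:
        if self.n_participants < 1:
            raise DesignError("n_participants must be >= 1")
        for f in (self.long_fraction, self.prior_infected_fraction, self.infection_prob,
                  self.negative_test_prob):
            if not (0.0 <= f <= 1.0):
                raise DesignError(f"fraction {f} outside [0, 1]")
        for lo, hi in (self.long_interval_days, self.short_interval_days,
                       self.infection_offset_days):
            if lo <= 0 or hi < lo:
                raise DesignError(f"invalid positive interval range ({lo}, {hi})")
        for lo, hi in (self.baseline_visit_offset, self.postdose1_visit_offset,
                       self.peak_visit_offset, self.late_visit_offset):
            if hi < lo:
                raise DesignError(f"invalid visit offset range ({lo}, {hi})")
        if as_day(self.study_start) > as_day(self.study_end):
            raise DesignError("study_start after study_end")

    @property
    def group_fractions(self) -> dict[tuple[str, str], float]:
        pf, lf = self.prior_infected_fraction, self.long_fraction
        return {
            ("long", "N"): lf * (1 - pf),
            ("long", "Y"): lf * pf,
            ("short", "N"): (1 - lf) * (1 - pf),
            ("short", "Y"): (1 - lf) * pf,
        }


def demo_design(seed: int = 0) -> CohortDesign:
    """Design emulating the scale of the published demo cohort (587 HCWs)."""
    return CohortDesign(n_participants=587, seed=seed)


@dataclass
class SyntheticCohort:
    """Generated source tables plus the per-participant ground truth."""

    design: CohortDesign
    metadata: pd.DataFrame
    serology: pd.DataFrame
    swab: pd.DataFrame
    symptom: pd.DataFrame
    truth: pd.DataFrame

    @property
    def experiments(self) -> dict[str, pd.DataFrame]:
        return {"serology": self.serology, "swab": self.swab, "symptom": self.symptom}

    def to_csv(self, directory) -> Path:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, df in [("metadata", self.metadata), ("truth", self.truth),
                         *self.experiments.items()]:
            _stringify_dates(df).to_csv(d / f"{name}.csv", index=False, lineterminator="\n")
        return d

    def to_sqlite(self, path) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        with sqlite3.connect(p) as con:
            for name, df in [("metadata", self.metadata), *self.experiments.items()]:
                _stringify_dates(df).to_sql(name, con, index=False, if_exists="replace")
        return p


def _stringify_dates(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    return out


def perturb_dates(
    metadata: pd.DataFrame,
    seed: int,
    *,
    month_col: str = "dose1_month",
    base_col: str = "dose_1_date",
    interval_cols: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Turn month-resolution dose-1 dates into fictional day-level dates.

    A day-of-month is drawn uniformly from 1..28 per participant (never
    29-31, so every month is valid) and appended to the ``YYYY-MM``
    first-dose month; each downstream date named in ``interval_cols``
    (mapping new column -> interval-in-days column) is recomputed as
    dose-1 date + interval, so the stored intervals are preserved
    exactly.
    """
    if interval_cols is None:
        interval_cols = {"dose_2_date": "interval_days"}
    if month_col not in metadata.columns:
        raise MissingColumnError(f"month column '{month_col}' not found")
    for newcol, ic in interval_cols.items():
        if ic not in metadata.columns:
            raise MissingColumnError(f"interval column '{ic}' not found")
    rng = np.random.default_rng(seed)
    out = metadata.copy()
    days = rng.integers(1, 29, size=len(out))
    base = pd.to_datetime(
        out[month_col].astype(str) + "-" + pd.Series(days, index=out.index).astype(str).str.zfill(2),
        format="%Y-%m-%d",
    )
    out[base_col] = base
    for newcol, ic in interval_cols.items():
        out[newcol] = base + pd.to_timedelta(out[ic].astype(int), unit="D")
    return out


def _largest_remainder_counts(n: int, fractions: list[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def generate_cohort(design: Optional[CohortDesign] = None) -> SyntheticCohort:
    """Generate the synthetic cohort tables; deterministic given the seed."""
    design = design or CohortDesign()
    design.check()
    rng = np.random.default_rng(design.seed)
    n = design.n_participants
    start, end = as_day(design.study_start), as_day(design.study_end)
    switch = as_day(design.variant_switch_date)

    groups = [("long", "N"), ("long", "Y"), ("short", "N"), ("short", "Y")]
    counts = _largest_remainder_counts(n, [design.group_fractions[g] for g in groups])
    interval_group = np.concatenate(
        [np.repeat(g[0], c) for g, c in zip(groups, counts)]
    )
    prior = np.concatenate([np.repeat(g[1], c) for g, c in zip(groups, counts)])
    width = max(4, len(str(n)))
    ids = np.array([f"P{i + 1:0{width}d}" for i in range(n)], dtype=object)

    months = rng.choice(np.asarray(design.dose1_months, dtype=object), size=n)
    lo_l, hi_l = design.long_interval_days
    lo_s, hi_s = design.short_interval_days
    intervals = np.where(
        interval_group == "long",
        rng.integers(lo_l, hi_l + 1, size=n),
        rng.integers(lo_s, hi_s + 1, size=n),
    )

    meta0 = pd.DataFrame(
        {
            "participant_id": ids,
            "interval_group": interval_group,
            "prior_infection": prior,
            "dose1_month": months,
            "interval_days": intervals.astype("int64"),
        }
    )
    derived_seed = (design.seed * 1_000_003 + 7) % (2**31)
    metadata = perturb_dates(meta0, seed=derived_seed)
    dose1 = metadata["dose_1_date"]
    dose2 = metadata["dose_2_date"]

    def _draw(lohi):
        return rng.integers(lohi[0], lohi[1] + 1, size=n)

    visit_days = [
        dose1 + pd.to_timedelta(_draw(design.baseline_visit_offset), unit="D"),
        dose1 + pd.to_timedelta(_draw(design.postdose1_visit_offset), unit="D"),
        dose2 + pd.to_timedelta(_draw(design.peak_visit_offset), unit="D"),
        dose2 + pd.to_timedelta(_draw(design.late_visit_offset), unit="D"),
    ]

    infected = rng.random(n) < design.infection_prob
    inf_offset = rng.integers(
        design.infection_offset_days[0], design.infection_offset_days[1] + 1, size=n
    )
    inf_date = dose1 + pd.to_timedelta(inf_offset, unit="D")
    latest = end - pd.Timedelta(days=design.evidence_scatter_days + 7)
    inf_date = inf_date.where(inf_date <= latest, latest)
    variants = np.where(inf_date < switch, design.early_variant, design.late_variant)

    pcr_delay = rng.integers(0, design.evidence_scatter_days + 1, size=n)
    seq_delay = rng.integers(0, design.evidence_scatter_days + 1, size=n)
    sym2_delay = rng.integers(1, design.evidence_scatter_days + 1, size=n)

    # anti-S geometric means per visit
    base_gm = np.where(prior == "Y", design.baseline_titer_gm[1], design.baseline_titer_gm[0])
    pd1_gm = np.where(prior == "Y", design.postdose1_titer_gm[1], design.postdose1_titer_gm[0])
    peak_gm = np.select(
        [
            (interval_group == "long") & (prior == "N"),
            (interval_group == "short") & (prior == "N"),
            (interval_group == "long") & (prior == "Y"),
        ],
        [
            design.peak_titer_gm_long_uninfected,
            design.peak_titer_gm_short_uninfected,
            design.peak_titer_gm_long_infected,
        ],
        default=design.peak_titer_gm_short_infected,
    )
    gms = [base_gm, pd1_gm, peak_gm, peak_gm * design.late_titer_decay]

    sero_records = []
    lag = pd.Timedelta(days=design.seroconversion_lag_days)
    sero_visit = np.full(n, -1)
    for v, (dates, gm) in enumerate(zip(visit_days, gms), start=1):
        noise = 10.0 ** rng.normal(0.0, design.titer_log10_sd, size=n)
        titers = gm * noise
        for i in range(n):
            d = dates.iloc[i]
            if prior[i] == "Y":
                anti_n = "positive"
            elif infected[i] and d >= inf_date.iloc[i] + lag:
                anti_n = "positive"
                if sero_visit[i] < 0:
                    sero_visit[i] = v
            else:
                anti_n = "negative"
            sero_records.append(
                {
                    "participant_id": ids[i],
                    "date": d,
                    "anti_s": float(np.round(titers[i], 3)),
                    "anti_n": anti_n,
                }
            )
    serology = pd.DataFrame.from_records(sero_records).sort_values(
        ["participant_id", "date"], kind="stable"
    ).reset_index(drop=True)

    # swab table: positive PCR + sequencing for the infected; sprinkled
    # negative PCRs elsewhere so that matching has decoys
    swab_cells: dict[tuple, dict] = {}
    neg_test = (~infected) & (rng.random(n) < design.negative_test_prob)
    neg_offset = rng.integers(7, 120, size=n)
    for i in range(n):
        if infected[i]:
            d_pcr = inf_date.iloc[i] + pd.Timedelta(days=int(pcr_delay[i]))
            d_seq = inf_date.iloc[i] + pd.Timedelta(days=int(seq_delay[i]))
            swab_cells.setdefault((ids[i], d_pcr), {})["pcr_result"] = "positive"
            swab_cells.setdefault((ids[i], d_seq), {})["sequencing"] = str(variants[i])
        elif neg_test[i]:
            d = min(dose1.iloc[i] + pd.Timedelta(days=int(neg_offset[i])), end)
            swab_cells.setdefault((ids[i], d), {})["pcr_result"] = "negative"
    swab = pd.DataFrame.from_records(
        [
            {"participant_id": pid, "date": d,
             "pcr_result": cells.get("pcr_result"), "sequencing": cells.get("sequencing")}
            for (pid, d), cells in swab_cells.items()
        ],
        columns=["participant_id", "date", "pcr_result", "sequencing"],
    ).sort_values(["participant_id", "date"], kind="stable").reset_index(drop=True)

    sym_records = []
    for i in range(n):
        if infected[i]:
            sym_records.append(
                {"participant_id": ids[i], "date": inf_date.iloc[i], "symptom": "Y"}
            )
            sym_records.append(
                {
                    "participant_id": ids[i],
                    "date": inf_date.iloc[i] + pd.Timedelta(days=int(sym2_delay[i])),
                    "symptom": "Y",
                }
            )
    symptom = pd.DataFrame.from_records(
        sym_records, columns=["participant_id", "date", "symptom"]
    )

    truth_records = []
    for i in range(n):
        if infected[i]:
            ep_start = inf_date.iloc[i]
            ep_end = ep_start + pd.Timedelta(
                days=int(max(pcr_delay[i], seq_delay[i], sym2_delay[i]))
            )
        else:
            ep_start = ep_end = pd.NaT
        events = [(dose1.iloc[i], 0, "V1"), (dose2.iloc[i], 0, "V2")]
        if infected[i]:
            events.append((ep_start, 1, f"I1[{variants[i]}]"))
        events.sort(key=lambda t: (t[0], t[1]))
        truth_records.append(
            {
                "participant_id": ids[i],
                "interval_group": interval_group[i],
                "prior_infection": prior[i],
                "dose_1_date": dose1.iloc[i],
                "dose_2_date": dose2.iloc[i],
                "n_episodes": int(infected[i]),
                "episode_start": ep_start,
                "episode_end": ep_end,
                "variant": str(variants[i]) if infected[i] else None,
                "seroconversion_visit": int(sero_visit[i]) if sero_visit[i] > 0 else None,
                "baseline_seropositive": bool(prior[i] == "Y"),
                "expected_history": ":".join(code for _, _, code in events),
            }
        )
    truth = pd.DataFrame.from_records(truth_records)
    truth["seroconversion_visit"] = truth["seroconversion_visit"].astype("Int64")

    return SyntheticCohort(
        design=design,
        metadata=metadata,
        serology=serology,
        swab=swab,
        symptom=symptom,
        truth=truth,
    )
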