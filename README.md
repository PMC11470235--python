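# cohortgram

Person-day *chronogram* tables for curating and analysing infection and
vaccination cohort studies.

Observational cohort studies (vaccine-response cohorts, healthcare-worker
surveillance, household transmission studies) accumulate data in awkwardly
disaggregated shapes: per-participant metadata in a clinical data-capture
system (REDCap or similar), and sparse date-stamped assay results — antibody
titers, PCR/antigen tests, symptom diaries, viral sequencing calls — spread
across LIMS exports. Translating a biological question ("did people with a
longer interval between vaccine doses mount higher peak antibody responses,
and does prior infection change that?") into analysis code over such data is
error-prone, chiefly because everything hinges on dates.

`cohortgram` rearranges all of it around a single invariant: **exactly one
row per participant per calendar day**, over an inclusive study span. On
that dense person-day grid,

* **assembly** broadcasts per-participant metadata and left-joins each
  sparse experiment table onto its `{participant, date}` keys, refusing
  duplicate keys, unknown participants and out-of-span observations loudly;
* **annotation** derives infection episodes (maximal clusters of evidence
  days separated by gaps ≤ `max_gap`), seroconversion windows
  (negative→positive marker transitions between blood draws, recorded as
  half-open intervals `(last_negative, first_positive]`), episode-level
  fills (e.g. a single sequencing day labelling a whole episode), cumulative
  vaccine/infection/exposure counts, and per-day **antigenic histories**
  such as `V1:I1[Delta]:V2` — the chronologically ordered exposure sequence
  up to each day;
* **sub-cohorting** follows a *filter → window → select* grammar: filter
  rows by a predicate, window each participant to signed day offsets around
  a reference event (a dose date, an episode onset, the *n*-th visit), then
  select one visit per participant so nobody contributes two results;
* **serialization** saves chronograms losslessly as an inspectable
  plain-text container (JSON manifest + collapsed metadata + sparse
  observation rows) whose size grows with observations, not with
  participants × days;
* a **synthetic cohort generator** emits REDCap/LIMS-shaped tables (CSV and
  SQLite) with known ground truth, so the entire pipeline is testable at
  desk scale with no external data.

## Worked example

Generate a 200-participant synthetic cohort (long vs short dose-interval
groups, with/without prior infection, 10% mid-study infections), assemble
it, annotate it, and compare peak anti-Spike titers 28–35 days after the
second dose:

```python
import cohortgram as cgm

cohort = cgm.generate_cohort(cgm.CohortDesign(n_participants=200, seed=7))
cg = cgm.assemble(cohort.design.study_start, cohort.design.study_end,
                  cohort.metadata, cohort.experiments)
cg = cgm.episodes_find(cg, cgm.EvidenceSpec({"symptom": ["Y"],
                                             "pcr_result": ["positive"],
                                             "sequencing": ["Alpha", "Delta"]}),
                       max_gap=7)
cg = cgm.episodes_find_seroconversion(cg, cgm.SeroconversionSpec("anti_n"))
cg = cgm.episodes_fill(cg, ["sequencing"])
cg = cgm.episodes_count(cg)
cg = cgm.vaccines_count(cg, ["dose_1_date", "dose_2_date"])
cg = cgm.exposures_count(cg)
cg = cgm.antigenic_history(cg, "sequencing_filled")

sub = cgm.filter_rows(cg, "prior_infection == 'N' and episodes_count == 0")
sub = cgm.window_by_metadata(sub, "dose_2_date", 28, 35)
sub = cgm.select_visit(sub, "anti_s", policy="first")
print(sub.data.groupby("interval_group")["anti_s"].median())
```

prints

```
interval_group
long     1817.786
short     791.781
Name: anti_s, dtype: float64
```

— the long-interval group's median peak titer is ~2.3× the short group's
among never-infected participants, recovering the effect the generator
embeds (geometric means 2000 vs 800). With `scipy` installed, an unpaired
two-tailed Wilcoxon rank-sum test on the same two columns
(`scipy.stats.mannwhitneyu(..., alternative="two-sided")`) gives
p ≈ 7e-22. One infected participant's end-of-study row looks like:

```
participant_id       date  episodes_count  exposures_count antigenic_history
         P0029 2021-09-30               1                3   V1:V2:I1[Alpha]
```

two vaccine doses, then an Alpha infection: three antigenic exposures.

The same workflow is available from the shell via the `cohortgram` CLI
(`generate`, `assemble`, `annotate episodes|sero|counts|history`,
`subcohort`, `summary`), with chronograms passed between subcommands as
saved container directories.

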