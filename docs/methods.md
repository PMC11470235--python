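# Methods

## The chronogram data model

A chronogram is a dense long-format table with exactly one row per
{participant, calendar day} over an inclusive span `[start, end]`, so its
row count is always `n_participants × n_days` and every participant's rows
form a contiguous, gap-free run of days. Dates are timezone-free calendar
days; every comparison in the package is day-granular, because the unit of
observation in cohort studies of this kind is the calendar date of a visit,
swab or symptom entry. The span is closed at both ends: a row is generated
for the start day and for the end day.

Three column roles live on the grid:

* **metadata** — constant per participant (group labels, dose dates).
  Registered by name in an attribute slot; validation enforces at most one
  distinct non-missing value per participant per metadata column (all-missing
  is allowed, since e.g. a third-dose date may be absent).
* **experiment** — sparse assay/diary observations, present on their
  observation day and missing elsewhere. Missingness is one canonical
  absent marker regardless of source encoding ("", "NA", NULL).
* **annotation** — columns derived by this package, tracked in an explicit
  registry so summaries and serialization can classify them. (The metadata
  registry alone would not distinguish derived columns from assay columns,
  so the annotation registry extends the attribute-slot idea symmetrically.)

Participant identifiers are opaque: never numerically coerced, so
REDCap-style ids with leading zeros survive round trips. The full uniform
grid is generated for every participant regardless of enrolment date;
masking pre-enrolment days is left to user filters, keeping the cardinality
invariant trivial to state and check.

Sub-cohort *views* (outputs of filter/window/select) relax the dense-grid
invariant but keep key uniqueness; they carry a provenance list recording
each step applied, which the serializer persists for audit.

## Assembly

`assemble(start, end, metadata, experiments)` builds the grid as the
Cartesian product of participants and days, broadcasts metadata, and
left-joins each experiment on `{id, date}`. All joins are guarded:

* duplicate `{id, date}` within an experiment, or a duplicate participant
  id in metadata, abort assembly naming the offending key — one row per
  key is the contract everything else relies on;
* participants present in an experiment but absent from metadata are
  refused rather than invented;
* observations dated outside the span are refused by default; an explicit
  option drops them with a logged count. Silent data loss in a curation
  tool is worse than a loud failure;
* result-column name collisions are refused, preserving one-table-per-assay
  provenance through column names.

`add_experiment` commutes with assembly: adding a table later is
cell-for-cell identical to having included it from the start (property
tested).

Date parsing in `read_table` accepts strict ISO-8601 by default; any other
dialect must be named explicitly via `date_format`. Ambiguous dialects are
never guessed, and parse failures are reported per cell with row indices.
Text columns whose every non-missing value is a full `YYYY-MM-DD` string
are auto-parsed; month-resolution strings like `2021-01` stay text.

## Episode detection

An evidence day is any day on which a scanned column's value matches one of
its declared positive values (exact equality after trimming and
case-folding; a regex mode exists for messier sources). Per participant,
evidence days are merged into maximal clusters in which consecutive
evidence days differ by at most `max_gap` days; each cluster is an episode
spanning first-to-last evidence day, numbered 1-based chronologically.
Days *between* evidence days inside a cluster belong to the episode even if
they hold negative tests — the maximal-cluster reading of searching
backwards and forwards in time. (The alternative — breaking episodes at
interior negative tests — is expressible by adding the negative values to a
separate scan and lowering `max_gap`, but is not the default.)

`max_gap` defaults to 7 days: symptoms, confirmatory testing and sequencing
of one infection are typically a few days apart, but no single number is
right for every pathogen, so the value is a required, visible parameter in
the CLI and is not hard-coded anywhere else (pathogen-specific reinfection
rules, e.g. 90-day definitions, are deliberately not built in — they are
just a `max_gap` choice). Episode end is the last evidence day; no fixed
episode length is imposed, and window operations can extend spans
downstream.

## Seroconversion

Serological transitions are detected separately from test-evidence
episodes because the implied exposure window — the gap between two blood
draws — is usually far wider than a test-confirmed episode, and conflating
the two would corrupt episode dating. Each negative measurement followed
by a positive at the participant's next measurement yields one window
`(last_negative, first_positive]`, half-open so a single date can never be
both boundaries. Participants positive at their first measurement are
flagged baseline-positive (prior infection, not an in-study conversion).
Missing marker values are skipped, never treated as negative.
Positive→negative reversion is flagged but creates no episode; repeated
neg→pos transitions all count. For exposure dating, a seroconversion-only
infection is dated at the first positive draw — the first day the infection
is evidenced, a deliberately conservative choice.

## Counts and antigenic histories

`vaccines_count`, `episodes_count` and `exposures_count` are per-day step
functions; all increment **on the event day itself** (dose day 0 counts as
post-dose). This ±1-day convention changes every downstream window, so it
is fixed package-wide rather than configurable. `exposures_count` is
defined as the row-wise sum `vaccines_count + episodes_count`.

The antigenic history string on day *t* lists all exposure codes with
event date ≤ *t*, joined by `:` — vaccines `V1, V2, …` in dose order,
infections `I1, I2, …` chronologically, with `I1[label]` when a filled
label column (typically sequencing) supplies a variant. Same-day
vaccine+infection ties order vaccine first and are logged. The format is
an invention of this package (round-trip parseable via `parse_history`);
nothing downstream depends on its details beyond the parser.

By default exposure counting and histories use test-evidence episodes only,
which keeps the invariant "history code count = exposures_count" exact;
`antigenic_history(..., include_seroconversions=True)` additionally counts
seroconversion windows that do not contain any detected episode start, for
studies relying on serology alone.

Annotations build on one another; calling them out of order raises an
explicit ordering error rather than producing silently wrong columns.

## Sub-cohorting

Filter → window → select. Windows are inclusive at both ends — "28–35
days post dose" means days 28 and 35 both belong — and offsets are signed,
so "before" needs no separate function. Participants lacking the window's
reference (missing dose date, no n-th episode, too few visits) are dropped
with a logged count: narrowing is the purpose of sub-cohorting, and
erroring would make routine analyses impossible. `select_visit` defaults
to the earliest in-window result (`first`), a deterministic tie-break;
`last` and `nearest(ref)` are available, with `nearest` breaking distance
ties toward the earlier date. For the classic post-second-dose peak
analysis, both the narrow `[28, 35]` and the wide `[21, 35]` windows are
reasonable conventions; this package's examples and acceptance checks use
`[28, 35]`.

## Serialization

The container is a directory of plain-text parts: `manifest.json`
(format tag `cohortgram-v1`, key names, span, registries, per-column
dtypes, provenance, SHA-256 checksums), `metadata.csv` (one collapsed row
per participant) and `observations.csv` (sparse rows). A row is saved iff
it carries a non-missing experiment/annotation value **or** is a change
point of a dense derived column (cumulative counts, history strings,
per-participant flags) — those columns are registered with their default
value and reconstructed by forward-fill on load. This keeps saved size
Θ(observations + events + participants) while remaining exactly lossless,
and it means annotation columns are restored verbatim, never recomputed:
loading can never silently change results after an algorithm update
(re-annotation is an explicit user action). Views additionally save their
key list, since their row set is not derivable from a span. Saving is
byte-deterministic; loading verifies checksums and the span/observation
consistency, so a tampered manifest fails loudly. One caveat: the CSV
encoding cannot distinguish an empty string from a missing value, which is
consistent with the canonical-absent convention but means experiment values
that are literally `""` are not representable.

## The synthetic cohort

The generator emulates the shape of a two-dose vaccine study in
healthcare workers. Defaults (all configurable in `CohortDesign`):
200 participants; 50% long (70–84 day) vs 50% short (21–28 day) dose
intervals — the 10–12 week vs 3–4 week policy split; 25% of each arm
previously infected; first-dose months January–March 2021 over a study
span of 2020-12-01 to 2021-09-30; four venepuncture visits (14–7 days
before dose 1, 20–27 days after dose 1, 28–35 and 70–84 days after
dose 2). Dose-1 dates are month-resolution plus a day-of-month drawn
uniformly from 1..28 (so every month is valid) and all downstream dates
are recomputed from the drawn date plus stored day intervals — mirroring
how publicly released month-only dates are made analysable without
altering any interval.

Anti-S titers are log-normal around group geometric means (log10 SD 0.15):
baseline 5 (uninfected) / 150 (prior-infected), post-dose-1 100 / 2000,
post-dose-2 peak 2000 (long, uninfected) vs 800 (short, uninfected) and
5000 in both prior-infected arms — i.e. the long>short effect is embedded
only in the uninfected stratum and is exactly zero in the prior-infected
stratum, so recovery tests can check both the presence and the absence of
an ordering. The model is not a claim about antibody biology; it is the
minimal monotone structure the recovery tests need, and the fourth visit
simply decays the peak by half.

10% of participants acquire a mid-study infection 21–140 days after
dose 1 (so infections can fall between doses, exercising history
ordering). Each infection emits symptom entries on days 0 and +1..3, a
positive PCR on day +0..3 and a sequencing call (Alpha before June 2021,
Delta after) on day +0..3 — deliberately scattered so episode detection
must merge them — plus anti-N seroconversion at the first visit ≥ 14 days
post-infection, if any. 20% of never-infected participants carry a
negative PCR as a matching decoy. Ground truth (episode span, variant,
seroconversion visit, expected end-of-study history string) is computed
from the event dates at generation time, independently of the annotation
code paths.

What the generator does **not** emulate: titer boosting by mid-study
infection, waning/boosting kinetics beyond one decay step, missed visits,
withdrawal, assay censoring at limits of detection, or multiple infections
per participant. Pipeline tests passing on this cohort therefore
demonstrate correctness of the date-aware bookkeeping — assembly,
merging, counting, windowing, serialization — not robustness to every
messiness of real study data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at n = 200
(ground-truth recovery; 100-seed effect recovery), at n = 587 for the
demo-scale SQL assembly, and batch 1000 random configurations per oracle
check; these sizes give exact, non-flaky checks at interactive runtimes.
There is no floating-point estimation anywhere in the core: all
computations are exact date/integer/string manipulations, so no tolerances
are needed — equality assertions are literal. Episode and seroconversion
detectors are checked against independently written brute-force oracles
(sort-and-split; consecutive-pair scan) rather than against themselves.

## Known limitations

* One grid means one span; studies with per-participant spans must use the
  union span plus filters.
* Dense grids cost memory at scale (587 participants × 304 days ≈ 180k
  rows is trivial; a million participants over years would warrant a
  sparse or chunked backend).
* `filter_rows` string predicates use `pandas.DataFrame.query` syntax,
  inheriting its quoting rules for odd column names.
* The history string's infection labels come from a filled column at the
  episode start date; if filling was skipped, infections appear unlabelled.
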