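# Methods

## Problem setting

A distributed research network standardises each institution's data to the
OMOP CDM and shares only analysis results. The schema nevertheless retains
columns among the 18 HIPAA identifier categories — event dates, sub-state
geography, provider and device identifiers — plus demographic attributes
and clinical order codes whose combination can single a person out. This
package measures that residual risk with statistical disclosure-control
metrics and quantifies what the stricter safe-harbor policy would remove.

## Variable classification

Columns are classified structurally (by schema position, never by content
inspection) into PHI, demographic QI, clinical QI or other. Dates and
sub-state geography are fixed as PHIs even though they behave like QIs,
following HIPAA's identifier list; the masking rule is a function of the
classification (date → year-only generalisation, other PHI → suppression,
QI → untouched). Two profiles ship:

- `synpuf5pct` — the 16 PHIs / 12 QIs present with complete values in the
  public SynPUF 5% OMOP v5.2.2 release (12 clinical tables); hard-coded.
- `omop_full` — a 45 PHI / 17 QI classification of the full v5.2 table
  set, shipped as an editable YAML document. The membership is an authored
  reconstruction (date and datetime columns, address fields, provider
  NPI/DEA, device identifiers; order codes and demographics as QIs); the
  45/17 totals are enforced at load so edits that change the contract are
  caught. Review it before relying on it for a concrete deployment.

Unlisted columns classify as `other` and are never analysis variables.
Surrogate keys are excluded outright: with them every record is trivially
unique and the metrics degenerate.

## Analysis datasets

Per-PHI limited data sets hold the PHI plus the five common demographics
(year of birth, gender, race, ethnicity, state), one row per row of the
PHI's table. Tables without a person reference are reached through their
natural event table: location attributes through `person`
(person→location), provider attributes through `visit_occurrence`
(visit→provider). Joins are left joins on unique keys, so the output row
count never exceeds the driving table's.

Scenario data sets combine eleven common variables (the five demographics
plus six common PHIs: month/day of birth, county, NPI, visit start/end
dates) with each scenario's own table contributing its date PHIs and
concept-id QI. The seven clinical QIs map one-to-one onto the seven
scenarios, which places `place_of_service_concept_id` on the death
scenario. The diagnosis scenario therefore has 14 columns. All
compositions are plain data (`ScenarioSpec`) and overridable.

Rows with a null in any selected column are dropped and counted
(complete-case analysis, matching a table subset chosen to be free of
missing values). One deliberate exception: the death scenario is driven by
the visit table — a mortality extract keeps the full visit history — with
the one-row-per-person death table joined outer and absent death dates
kept as the shared token `(none)`. Dropping them instead would silently
restrict the scenario to deceased patients and shrink it by three orders
of magnitude; an absent death is shared information, not a data defect.

## Masking

`limited` is the identity; `safe_harbor` maps every date-kind PHI to the
literal token `YYYY-**-**` and every other PHI to the single token `*`.
Suppressed values share one token rather than per-row nulls so a
suppressed column contributes nothing to distinguishability. Both
transforms are row-aligned (row i maps to row i), idempotent, and
coarsenings of the equivalence-class partition — the properties the gap
metrics and paired sampling rely on. The HIPAA age-90 aggregation rule is
*not* applied to `year_of_birth` (it survives masking as a QI); a custom
policy can override any column's rule.

## Metrics and numerical conventions

Equivalence classes are computed in one hash-grouping pass (pandas
groupby on raw tokens, missing values forming their own key; no
normalisation beyond what the tokens already are). Conservation
Σ k·c_k = N is validated on every profile at construction. "Minimum cell
size k" reporting uses the exact-size convention (records in classes of
size exactly k); a cumulative ≤ k mode exists behind a flag. Percentages
are carried at full floating precision and rounded half-even to 3
decimals only when reports are rendered. Published audit tables mix
truncation and rounding at the third decimal, so comparisons against
printed values use a ±0.005 percentage-point tolerance.

A profile of a 5-million-row, 14-column table is a single group-by pass
and completes in minutes on one CPU; nothing in the package does pairwise
work (the O(N²) oracle exists only in the test suite).

## Paired sampling

Sampling is without replacement with one index set per iteration shared
between the limited dataset and its masked image. Pairing is a design
choice: under a coarsening mask a record unique in the masked sample is
necessarily unique in the raw sample on the same rows, so every
per-iteration gap is ≥ 0 and between-dataset sampling noise cancels. An
unpaired mode exists for sensitivity analysis. Iteration r draws from a
substream keyed on (master seed, dataset name, n, r), so the grid is
stable under reordering; SD uses the n−1 denominator over the 100
iteration counts. When n exceeds the dataset size the cell is recorded as
not-applicable rather than resampled — there is no defensible way to draw
a without-replacement sample larger than the data.

Rows are factorised to class codes once; each iteration is a bincount
over the sampled codes, O(N) regardless of column count.

## Synthetic generator

The generator emulates the structural features that drive disclosure
risk in a claims-derived CDM, not clinical content:

- **Event window** 2008-01-01..2010-12-31 (1096 distinct dates), uniform
  event dates; end dates are start + a small offset (visits 0–7 days,
  conditions/devices 0–14, drug exposures 0 — dispense lines close the
  same day, which keeps drug start/end EC structure identical, as real
  claims extracts show).
- **Per-person multiplicity** differs by table: exactly one row per person
  in `person`, at most one in `death`, Poisson (optionally zero-inflated)
  counts elsewhere. The `synpuf_like` preset uses rates derived from the
  published per-table record volumes of the SynPUF 5% release divided by
  its 25,200 persons (visits 48.4, conditions 128.2, procedures 120,
  measurements 29.4, observations 16.7, drug 9.0 with 30% structural
  zeros, device 3.8 with 50% zeros; death fraction 1155/25200).
  `synpuf_like_small` keeps those multiplicities at 2,000 persons for
  tractable end-to-end runs; `toy` (40 persons) is the unit-test fixture.
- **Cardinalities**: gender 2, ethnicity 2, race 5, state 50, county 300,
  order codes 1000–4000, ~20 providers per person — chosen once for
  US-claims realism; all configurable per column.
- **Skew**: codes draw from a Zipf-like rank-frequency law (exponent 1 by
  default) since real order-code usage is heavily skewed.
- **Determinism**: one master seed; each table uses an independent
  substream keyed by a stable hash of its name, so adding a table never
  perturbs the others. Identical config + seed gives byte-identical
  tables.

What the generator does **not** emulate — and what passing tests on it
therefore cannot show: diagnosis–drug coherence or any longitudinal
disease model; duplicate same-day event lines for the same person (real
claims repeat identical rows, which lowers limited-level uniqueness of
date variables below what independent draws produce); realistic
geographic population weights; free-text fields. Results on synthetic
data support the *structural* findings (single- vs multi-occurrence
contrast, sampling trends, coarsening behaviour), not magnitude estimates
for any real dataset.

## Problem sizes

The shipped test suite and the acceptance script run the pipeline at
2,000 persons (~700k event rows) with sampling grids up to n = 100,000 at
100 iterations, and qualitative checks at 300–1,000 persons over 5 seeds
— sizes chosen so a complete run is a coffee-break on one CPU while
leaving every per-person multiplicity at its realistic value. Equal-n
comparisons are made only while n is a small fraction of N (≤ ~15% here):
as n approaches N a without-replacement sample exhausts the data and
every dataset's sampled uniqueness converges to its full-data value,
which is the regime the full-sample consistency test covers.

## Known limitations

- The full-CDM (45/17) classification is a reconstruction, not an
  authoritative list; treat it as a starting point.
- Scenario compositions (which PHIs/QIs accompany each scenario) are
  documented defaults, overridable in config.
- Risk is measured as uniqueness/cell-size only — no l-diversity,
  t-closeness or differential-privacy accounting, and no
  timespan-dependent analysis (the generator's fixed 3-year window would
  not support it).
- Masking covers the two HIPAA levels plus per-column overrides; no
  k-anonymisation algorithms or date shifting.
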