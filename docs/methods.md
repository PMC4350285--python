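# Methods

This note documents the analytical model implemented by `eolcare`, the
conventions it adopts where the underlying administrative rules are
ambiguous, and what the synthetic-data generator does and does not emulate.

## Coordinate system

All end-of-life quantities are computed in *constructed months*: 30-day
blocks counted backwards from, and including, the day of death. Month 1 is
days 0–29 before death, month *m* is days 30(m−1) to 30m−1. The default
observation window of 6 constructed months therefore spans exactly 180
calendar days ending on the day of death; the 12-month eligibility window
spans 360 days and the 18-month residence window 540 days. One coordinate
system is used everywhere — eligibility, comorbidity look-backs, costing and
trajectories — so window boundaries compose without off-by-one seams.

## Cohort model

Base eligibility applies five criteria in a fixed order (entitlement,
residence, age, death window, minimum claims); every failure is recorded but
the first one names the exclusion. "Full entitlement" is read strictly: the
Gold entitlement level must cover every day of the last 360, with a
configurable grace allowance defaulting to zero.

Cancer ascertainment accepts either a notifiable-cancer registry record
(diagnosis window default Jan 1994 – Dec 2008) or a notifiable cancer coded
as underlying cause of death (cause-coded period default through Dec 2007; a
missing cause is non-informative). The non-cancer screening hierarchy then
runs, in order: hospital procedure/diagnosis codes (episodes admitted
Jul 2000 – Dec 2009), class-L dispensings (Jul 2004 – Dec 2009), cancer-
indicative service items (same window), and non-notifiable cancer causes of
death. Within the drug step, intravenous fluorouracil (L01BC02) carries its
own exclusion reason; the cream form is retained via the exception list, and
any other form of L01BC02 is treated as an ordinary excluding class-L drug —
the conservative reading of a cream-only exception. The cancer-indicative
service set is inherently a clinical-review product, so it is a first-class
configuration input; the shipped default names the synthetic catalogue's
chemotherapy, radiation-oncology, cancer-surgery and multidisciplinary-
conference items.

### ICD-10 range semantics

Code-set expressions mix 3-character category ranges (`C00-C43`), single
categories, single one-decimal subcodes and one-decimal ranges
(`D46.0-D46.4`). A category range matches on the 3-character category; a
decimal range matches on category plus first decimal digit. A bare
3-character code matches a decimal range only when its entire `.0`–`.9` span
is contained (so `D48` falls inside `D47.4-D48.9` but `D46` is not inside
`D46.0-D46.4`). Malformed codes always raise — membership is never silently
false. An enumeration oracle over all categories A00–Z99 plus decimal
subcodes pins these semantics in the test suite.

## Classification

Cause-of-death groups use literal code sets (heart failure, cerebrovascular
I60–I69, coronary heart disease, COPD J40–J44, dementia, cancer = the
notifiable set); all other well-formed codes map to `other`, keeping the
grouping total and single-valued.

Medicines map to four expected end-of-life use categories via longest-prefix
ATC matching; unmapped codes are reported explicitly rather than defaulted.
The shipped prefix table is a starting point seeded from the category
definitions and is intended to be replaced by an expert-reviewed mapping
(the scheme is a judgement product, not derivable from code lists alone).
Service items map by exact identifier; admin/billing items are retained for
costing but never counted as resource use.

The Charlson index uses hospital diagnoses from episodes admitted in months
18–7 before death (days 180–539); with no admissions in that window the
score is *not calculable* — a distinct reporting category, not zero. All 50
diagnosis fields are used by default (configurable to principal-only). The
medication-based score counts distinct comorbidity categories among
dispensings in months 12–7 (days 180–359). Both mappings ship as condensed
prefix adaptations of published coding algorithms and are fully replaceable
by user-supplied files; the condensation trades coverage of rare subcodes
for a compact, reviewable table.

## Costing model

All costs are expressed at the 2009/10 financial-year price level.

**Medicines.** Benefit paid is inflated monthly within the supply financial
year (July–June) — one application of the supply year's monthly rate per
month remaining after the supply month — then annually over later financial
years. A March 2005 supply thus compounds three monthly factors
(April–June) and five annual factors, giving 1.0114; a June 2010 supply
returns exactly 1. The concessional co-payment ($6.00) is added at its
nominal value where applicable (an `inflate_copay` switch applies the
medicines factor instead).

**Services.** Sector-specific annual rates chain over November–October
schedule years strictly after the year containing the service date (fee
schedules update every November); the dental example for March 2005 chains
all five rates to 1.2491. Services are bulk-billed, so no co-payment is ever
added.

**Hospital episodes.** A bed-day is *observed* when its calendar date lies
inside the observation window. Length of stay is separation minus admission
in days, with same-day stays counting as one day; equivalently an episode
occupies calendar days admission … admission+LOS−1. SNAP (sub- and
non-acute) episodes cost `0.0424 × $11,582` per observed day — exactly
linear in observed days. Acute episodes cost cost-weight × base ($4,092
excluding ED only; $3,840 excluding ED and ICU available by configuration —
the larger base is the default because ICU time is not separately observed
while ED presentations are costed separately), plus the DRG's outlier
per-diem for observed days beyond its trim point up to day 120, plus an
uncapped $200/day beyond day 120 (deliberately not capped at 365 days, to
avoid under-costing very long stays). When an episode begins before the
window, the inlier component is prorated by observed/total inlier days and
per-diems accrue only for observed days. Per-DRG weights, trim points and
per-diems are a required parameter file; the shipped table is synthetic
(real casemix costing tables are proprietary) with realistic magnitudes.

**ED presentations.** $396 per presentation, weighted by mode of separation
(weights default to 1; `normalize_ed_weights` rescales a relative weight
vector so a configured outcome mix averages to cost 1, preserving the mean).

**Totals.** Per-person totals sum medicines, out-of-hospital services,
hospital and ED costs. Service claims flagged in-hospital, or dated inside
any of the person's episodes, are costed but excluded from the total
(assumed captured by the casemix cost). For private-hospital episodes the
summed nominal benefit of private-flagged in-episode dispensings is deducted
from that episode's cost, floored at zero. Every event is emitted as a
ledger item with an itemized component breakdown, so the total is
re-derivable as an accounting identity — this identity is asserted across
whole synthetic bundles in the test suite. Costs are kept at full precision
internally and reported to cents (banker's rounding).

## Utilization metrics

Hospital stays chain episodes: a transfer separation followed by an
admission within the configurable gap (default 0 days, i.e. same-day)
continues the stay. Overlapping non-transfer episodes are warned about and
kept separate. The ED-admission cross-check counts admissions twice — ED
records with outcome `admitted` versus episodes with source of referral
`ed` — because the ED collection covers only a subset of departments, so the
episode-based count is the more complete of the two.

Person-years are days of observation / 365.25. Quality indicators are
count-of-events ≥ threshold within a days-before-death window; the shipped
default set (ED visit and hospital admission in the last 30 days, > 14
hospital days in the last 30, chemotherapy in the last 14, opioid dispensing
in the last 30) mirrors indicator constructs from the end-of-life quality
literature, with windows and thresholds explicitly placeholders pending
expert calibration — `derive_threshold` provides the nearest-rank percentile
(smallest element with at least p% of the sample at or below it) for turning
the cohort's own utilization distribution into cut-offs.

## Synthetic-data generator

The generator emulates the *structure* of the linkage, not any real
population's joint distribution. Per person it draws a death date uniform in
the study window, age at death from a normal (mean 86, SD 7) truncated to
65–105, sex with cohort-specific male fractions (0.68 cancer / 0.51
non-cancer), entitlement and residence histories with small configurable
downgrade/short-residence rates (0.03 / 0.02) that exercise the eligibility
rules, and area attributes with configurable missingness. Claim counts are
Poisson per constructed month, with per-person-month rates calibrated to the
per-person last-6-month claim volumes of an elderly decedent cohort: 17
medical services, 7 dispensings, 0.49 hospital episodes and 0.21 ED
presentations per person-month, and a final-month intensification multiplier
(default 1.5) emulating terminal escalation so trajectory metrics have a
gradient to detect. Cause-of-death codes are only generated for deaths in
the cause-coded period (through 2007), reproducing the truncated-COD
missingness pattern.

The cancer fraction (default 0.4) fixes exactly which persons are built on
the cancer template: every such person carries a notifiable registry record
or (for ~15% of pre-2008 deaths) a notifiable cause of death alone.
Non-cancer-template persons are constructed to screen clean — no class-L
dispensings, no cancer-indicative items, no cancer codes in episodes — so
cohort outcomes on generated data are predictable by construction; the 14
planted scenarios then exercise each rule and costing branch one at a time,
and the test suite requires 100% of them to land in their declared buckets.
Admissions are serialized per person (no overlapping episodes), every
admitted ED visit gets a matching ED-referred episode, and additional
ED-referred episodes arise independently, so the admitted-patient count
dominates the ED-collection count as in real linkages.

What the generator does **not** emulate: marginal distributions of real
cohorts beyond the configured fractions, diagnosis-code co-occurrence
structure, seasonal or calendar-time effects, provider/facility clustering,
and linkage error (tables arrive perfectly linked). Passing tests therefore
demonstrate correctness of the *rules and arithmetic* on schema-faithful
data, not fidelity of any simulated population.

## Problem sizes and determinism

The test suite and examples run at 12–200 decedents; at 200 decedents the
full five-stage pipeline completes in well under a minute on a single CPU
and is byte-identical across runs with the same seed and configuration
(asserted via SHA-256 checksums of every output file). All randomness flows
from one `numpy` generator seeded from the run configuration.

## Known limitations

- The class-L exception list, cancer-indicative service set, medicine
  category mapping and comorbidity mappings are configuration, shipped with
  defaults suitable for the synthetic catalogue; real analyses must supply
  curated versions.
- Costing covers the payer perspective only: no patient out-of-pocket
  beyond the flat concessional co-payment, no discounting, no outpatient
  hospital costing beyond its assumed capture in service claims.
- Episodes are costed independently; a multi-episode stay crossing the
  120- or 365-day marks is handled per episode, not per stay.
- Regression modelling of factors associated with outcomes is out of scope;
  the pipeline exports analysis-ready tables instead.
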