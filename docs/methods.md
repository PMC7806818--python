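# Methods

This note records the models and procedures `mmpathways` implements, the
assumptions and conventions behind them, what the synthetic generator
does and does not emulate, and the numerical choices a reviewer would
want to see stated.

## Cohort selection

A patient indexes on the earliest diagnosis claim carrying an MM code
(ICD-9 203, 203.0, 203.0x), any position, any setting.  Members must
satisfy, in this order (the first failed rule is the primary exclusion
reason):

1. an MM index claim exists, inside the study window 2007-01-01 to
   2015-12-31;
2. age ≥ 18 at index (completed years, floor);
3. enrollment begun ≥ 365 days before index ("12 months" is
   operationalized as a fixed 365-day window — calendar-month arithmetic
   is ambiguous; configurable via `lookback_days`);
4. no diagnosis claim with any other primary malignancy (ICD-9 140–208
   excluding the MM index codes) before index.  One claim suffices
   (conservative); `prior_cancer_min_claims` can require more;
5. no plasma-cell-leukaemia or other-immunoproliferative code (203.1x /
   203.8x) within 61 days of the first MM claim ("within 2 months" as a
   fixed-day window, configurable);
6. at least one further MM claim strictly after index;
7. at least one dispensing of a dictionary drug on/after index
   (same-day-as-index counts: first-line can start at diagnosis).

Every input patient lands either in the cohort or in the exclusion log
with all triggered rules; the partition is exact and order-independent
(patients are processed in sorted-id order).

Follow-up runs from index to the first of death, dis-enrolment, or the
administrative censor (2017-12-31); years use 365.25 days.  The diagnosis
era splits at 2012-06-01 (first post-bortezomib index date).  ASCT is the
first transplant procedure on/after index; earlier procedures are
ignored.

## Line-of-therapy algorithm

Each dispensing covers `[date, date + days_supply − 1]`.  A line starts
at its first dispensing and accumulates a drug set; it ends at the
earliest of:

* **gap** — ≥ 60 consecutive days with no coverage from any drug of the
  line.  The end date is the last covered day; the next dispensing (even
  of the same drug) opens the next line.  A 59-day gap does not end a
  line; a 60-day gap does.
* **late addition** — a dispensing of a drug outside the line's set
  strictly more than 90 days after line start.  Day 90 joins the line;
  day 91 opens a new one.  The old line ends the day before the new
  dispensing.
* **death** — attributed to the line even when it falls inside a trailing
  gap (there is no "untreated" state in the model); the end date is the
  earlier of the last covered day and the death date.
* **data end** — end of follow-up before a 60-day gap can be observed.

Conventions the published rules leave open, fixed here:

* Gaps are measured in days *without coverage* (the standard claims
  convention), not between dispense dates; `gap_basis="dispense_date"`
  switches to the latter for sensitivity analysis.
* Dispensings are processed in calendar-day groups, atomically: if any
  drug dispensed on a day triggers the late-addition rule, the whole
  day's dispensings open the new line together.  Carried-over drugs join
  the new line only through their own dispensings on/after the switch
  date (regimen-switch semantics).
* A trailing no-treatment period ≥ 60 days before censor closes the last
  line with reason `gap` (no successor line); shorter trailing periods
  give `data_end`.
* ASCT never opens or closes a line — it is a journey annotation and a
  stratum, not a regimen.
* A steroid-only episode starting > 90 days into a chemo line is a new
  line under these rules (the "new treatment" reading).  Whether such an
  episode is really maintenance is not decidable from claims; we take
  the literal rule and note the ambiguity.

The implementation is validated against an independent day-by-day
simulation oracle (walk every calendar day, track covered days, apply
the rules literally) on 1,000 randomized small claim sets, exact
equality.

### Regimen classes

NA = ≥ 1 novel agent (bortezomib, thalidomide, lenalidomide) and no
chemotherapy; CCNA = both; CA = chemotherapy only; SA = steroids only.
Steroids never demote a class.  Lenalidomide counts as a novel agent for
classification even though it was not reimbursed first-line in the study
setting — the generator reflects the reimbursement reality, the
classifier stays general.  Named regimens follow the published first-line
taxonomy with the melphalan triple matched before the generic
bortezomib + thalidomide rules so every printed label is reachable;
chemo-only sets split by the number of distinct cytotoxics.

## Comorbidity

The CCI uses the Deyo ICD-9-CM adaptation (17 condition groups, weights
1/2/3/6, shipped as an editable data file).  Claims strictly before
index and within 365 days contribute; each group counts once; severe
forms supersede mild ones (complicated diabetes, moderate/severe liver
disease, metastatic tumor).  The malignancy and metastatic groups are
excluded by default: every member has MM, so including them adds a
constant 2 and the published score means (0.6–1.9) indicate they were
not counted.  `include_malignancy=True` restores the textbook score.

The four MM-associated comorbidities (anemia 281/283/284/285/776, renal
failure 586, pneumonia 486, fracture 800–829) flag on ≥ 3 outpatient
claims on *distinct dates* (repeat same-day lines are one visit) or ≥ 1
inpatient claim, in a window that runs through the index date itself
(the published table reports comorbidity "at diagnosis").

## Disease-progression model

States are `L1, L2, L3, DEATH, CONTINUE`; lines beyond the third fold
into L3 occupancy, and death after the third line is attributed to L3.
`DEATH`/`CONTINUE` are absorbing.  The "Markov model" is estimated as an
embedded discrete multinomial over line-indexed states: transition
probabilities are empirical fractions with binomial standard errors
`sqrt(p(1−p)/n)`.  No time-homogeneous rate matrix or smoothing is
fitted — the published presentation is branch percentages and median
inter-line gaps, so sojourn-time summaries (months between line starts,
median/IQR, at 30.4375 days per month) stand in for rates.  Estimation
is purely empirical, stratified by period × ASCT × first-line class by
default; pooled counts equal sums over strata by construction.

Sankey graphs place L1/L2/L3 at depths 0/1/2 with a separate
DEATH/CONTINUE node per source depth; links carry counts and branch
percentages (1 decimal).  Flow conservation (entrants = movers + deaths
+ continuers) is asserted at every non-absorbing node on every export.

## Synthetic generator

The generator states a world and realises it exactly; truth is always
the *realised* journey, serialized next to the bundle.

Calibrated defaults (from the published cohort tables): period mix
0.545/0.455 (pre/post), ASCT probability 0.110/0.150, per-stratum
age ~ Normal (e.g. 53.9 (7.2) pre-ASCT, 57.0 (7.7) post-ASCT, 69.4–69.6
(11.6) non-ASCT), male fractions 0.525–0.585, first-line class mixes per
stratum (e.g. post/non-ASCT NA 0.5455, CCNA 0.2946, CA 0.0278, SA
0.1321; post/ASCT NA 0.761), and the post-period L1 branch fractions
0.587/0.033/0.380 (ASCT; the printed branches sum to 98%, the remainder
is assigned to continuation) and 0.519/0.330/0.151 (non-ASCT).  L1→L2
sojourns are lognormal with median 17.5 (pre) / 11.6 (post) months,
L2→L3 14.9 / 6.8, log-scale σ = 0.6.  Rows of L2/L3 and the pre-period
matrices are not printed in the source tables; they are repository
choices consistent with the reported overall death fractions, documented
in `simulate.py`.  In-line death times are lognormal (median 8 months,
σ = 0.8); the diagnosis-to-transplant delay is lognormal (median 9.6
months, σ = 0.6).

Realisation: dispensings every 28 days with 28-day supply (continuous
coverage); all drugs of a regimen share the schedule.  Inter-line
transitions are realised either as a 75-day no-coverage gap or, with
probability 0.5 when the sojourn allows, as a drug switch > 90 days
after line start with seamless coverage — both unambiguous under the
60/90-day rules, so the pipeline recovers truth journeys and line
boundaries exactly.  Sojourns are clamped to ≥ 92 days and death dwells
to ≥ 14 days to keep realisations feasible (touches ~1% of draws at the
default medians).  Index dates are drawn uniformly in the period window,
shifted earlier when needed so the journey completes before the censor;
if even the earliest index cannot fit, the realisation is truncated at
the censor and the truncated journey becomes truth.  Each patient has a
private random stream derived from `(seed, patient index)`: identical
seeds give byte-identical bundles, and growing `n` never perturbs
earlier patients.

Planted exclusion violations are deterministic in number (a count per
rule, assigned to the first patients in index order), each violating
exactly one rule, so excluded-patient counts equal plant counts exactly.

What a green round-trip test establishes — and what it does not: the
generator produces clean coverage patterns, no inpatient cycle
fragmentation, no dose changes, no partial adherence, no transfer
between settings, and boundary cases (exactly 60/90 days) only via
dedicated fixtures.  Recovery on this world validates the *rules as
implemented*, not robustness to the messiness of real claims.

## Reporting and suppression

Tables render counts as `n (pct)` with the column N as denominator;
percentages within a categorical breakdown sum to 100 ± rounding.  Every
non-zero count below the threshold (default 3) is masked with the
self-describing token `"<3"` — percentage included; zeros render
explicitly as `0 (0.0)`.  Month conversions use 30.4375 days everywhere.

## Known limitations

* ICD-9 only; no ICD-10 era, no Elixhauser.
* No survival-curve estimation, covariate-adjusted multistate hazards,
  or prediction beyond observed follow-up.
* Inpatient chemotherapy cycles are represented as dispensings with
  days-supply; real inpatient administration records are messier.
* The generator's realism extends exactly as far as the pipeline's
  decision points; it is not a population simulator.
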