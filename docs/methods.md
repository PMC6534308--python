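# Methods

## Scope and data model

`demorates` estimates period fertility (ASFR, TFR, GFR) and childhood
mortality (NNMR, PNMR, IMR, CMR, U5MR) directly from retrospective birth
histories, in the occurrence/exposure framework used by the major
household-survey programmes.  Inputs are rectangular tables in the DHS
recode convention: a women table (one row per respondent, wide
birth-history columns `b3_01..b3_20` and `b7_01..b7_20`) for fertility and
a births table (one row per live birth, `b3` date of birth, `b7` age at
death in completed months, absent for survivors) for mortality.  All dates
are century month codes (CMC), months since January 1900 with January
1900 = 1.  Column matching is case-insensitive, since recode releases vary
in case; any survey with the same content can be used by naming its
columns (cluster, stratum, weight, interview date, dates of birth, age at
death).

Events are assumed fully dated: DHS/MICS recodes impute incomplete dates
before release, so no imputation is attempted here.  Women missing the
interview or own-birth CMC are excluded from fertility with a logged
count; mortality does not need the mother's date of birth.

## Reference windows

A run covers a window of `period` consecutive months (fertility default
36, mortality default 60).  By default the window ends the month before
each respondent's interview — the interview month is excluded because it
is only partially observed — so windows are per-respondent.  A fixed
calendar end may be given as `YYYY-MM`; that month is the last included
month and is shared by all respondents.  The reported "average reference
period" is the decimal year of the reference end (the unweighted mean
interview CMC, or the fixed end) minus `period/24` years.  A fixed end
inside or after the fieldwork span triggers a warning but not an error,
since mis-specified calendars (e.g. non-Gregorian CMCs) produce exactly
that symptom.

## Fertility estimation

In month m a woman born in month d has completed age m − d months and
belongs to age group a ∈ {0..6} iff 180 + 60a ≤ m − d ≤ 239 + 60a; the
month her age reaches 240 already belongs to 20–24 (completed-age rule).
Her exposure E_a is the count of window months in group a divided by 12;
one woman can contribute to two adjacent groups.  A birth in month b falls
in group ⌊(b − d)/60⌋ − 3; births with the mother outside 15–49 at
delivery are dropped and counted in the run log rather than folded into
15–19.  Twins count twice.  Then

    ASFR_a = 1000 Σ w B_a / Σ w E_a,   TFR = 5 Σ_a ASFR_a / 1000,
    GFR    = 1000 Σ_a B_a / (Σ_a E_a − E_45–49),

with w the normalized design weight (raw weight / 10^6 by default, the
DHS `v005` convention; the divisor is configurable for surveys whose
weights are already on a natural scale).  The GFR denominator excludes
only the 45–49 exposure while the numerator keeps all births, implementing
the estimator as conventionally printed in DHS tabulations.

For ever-married samples the all-women factor (a percentage ≥ 100, one
per woman, e.g. `awfactt`) multiplies exposure only: never-married women
contribute exposure but, by construction of such samples, no births.  With
all factors at 100 the adjustment is a no-op.  Class (domain) runs — urban
/rural, region, wealth quintile — estimate each class independently on its
subset, and the matching class-specific factor variable should be supplied.

Reported N and WN are unweighted and weighted woman-years per age group,
rounded to integers; multi-group totals (TFR, GFR) sum the rounded group
values, which keeps "GFR N = TFR N − 45–49 N" an exact integer identity.

## Childhood mortality estimation

Component death probabilities p_i are computed for the eight age segments
(completed months, half-open):

| i | segment | a_l | a_u |
|---|---------|-----|-----|
| 1 | 0       | 0   | 1   |
| 2 | 1–2     | 1   | 3   |
| 3 | 3–5     | 3   | 6   |
| 4 | 6–11    | 6   | 12  |
| 5 | 12–23   | 12  | 24  |
| 6 | 24–35   | 24  | 36  |
| 7 | 36–47   | 36  | 48  |
| 8 | 48–59   | 48  | 60  |

For a window of months [s, L] and a segment [a_l, a_u), a child born in
month b belongs to

- cohort 1 iff s − a_u ≤ b ≤ s − a_l − 1,
- cohort 2 iff s − a_l ≤ b ≤ L − a_u,
- cohort 3 iff L − a_u + 1 ≤ b ≤ L − a_l + 1,

and otherwise contributes nothing to that segment.  The three intervals
tile the feasible range with no gap or overlap; cohort 3 is one month
wider than cohort 1, because a child born the month after the window
closes still has segment-time overlapping the window's final month (the
boundary convention is fixed by reading the window ends as month
boundaries, which reproduces the standard worked cohort ranges month for
month).  Cohort 2 contributes full exposure and deaths; cohorts 1 and 3
contribute half the exposure and half the deaths.  When the window ends at
the survey, cohort-3 deaths instead count fully: deaths that cohort will
still suffer inside the segment after the interview are unobserved, so the
observed deaths are treated as half the cohort's eventual total.  A death
joins segment i iff a_l ≤ b7 < a_u and the child is in one of that
segment's cohorts; no separate calendar check on the death month is
applied, as the cohort construction embodies period attribution.

p_i is the weighted death sum over the weighted exposure sum; the reported
unweighted tallies keep the half-unit cohort weights, hence half-integer
death counts.  The rates follow

    NNMR = 1000 p_1,  IMR = 1000 (1 − Π_{1..4}(1−p_i)),  PNMR = IMR − NNMR,
    CMR  = 1000 (1 − Π_{5..8}(1−p_i)),  U5MR = 1000 (1 − Π_{1..8}(1−p_i)),

computed from unrounded probabilities, which makes PNMR = IMR − NNMR exact
and (1 − U5MR/1000) = (1 − IMR/1000)(1 − CMR/1000) hold to rounding error.

N and WN for a rate count each distinct child once across the rate's
constituent segments (NNMR: 1; PNMR: 2–4; IMR: 1–4; CMR: 5–8; U5MR: 1–8),
at the child's largest cohort exposure weight there, so single-segment
rates reproduce the segment exposure totals.  Published tabulations use an
unstated reduction for multi-segment rates that this choice approximates
but does not exactly reproduce.

## Sampling errors

ASFR and GFR are ratio estimators r = y/x; their SE uses Taylor
linearization over (stratum h, cluster i) weighted totals y_hi, x_hi:

    se²(r) = (1/x²) Σ_h [ m_h/(m_h−1) ( Σ_i z_hi² − z_h²/m_h ) ],
    z_hi = y_hi − r x_hi,

with m_h the clusters in stratum h.  Strata with a single cluster abort
with an explicit "lonely PSU" error; an opt-in `collapse_strata` merges
singletons with their sort-order neighbour.

TFR and the mortality rates use a non-stratified delete-one-cluster
jackknife: each of the k replicates re-runs the full tally with one
cluster removed (no leave-one-out shortcut — transparency over speed), and

    se²(r) = Σ_i (k r − (k−1) r_(i) − r)² / (k (k−1)).

Class-level runs replicate only over the clusters present in the class.

DEFT is the design SE over a simple-random-sampling baseline.  The
baseline is not canonically defined for these indicators; the package
uses: for ASFR/GFR, the same linearization with every woman her own PSU in
one stratum; for the TFR, the per-woman linearized contribution
u_i = 5 Σ_a (b_ia − (B_a/E_a) e_ia)/E_a in a one-stratum
elements-as-PSUs formula; for the mortality rates, the binomial proportion
se = √(r(1000−r)/n) on the per-1000 scale with n the unweighted children
contributing.  Published DEFTs for composite rates therefore need not be
reproduced exactly.  Confidence intervals are r ± z_{α/2} se; the lower
bound is not floored at zero.  RSE = se/r.

## Synthetic surveys

The generator emulates a two-stage design — default 4 strata × 10 clusters
× 25 women, interviews uniform over Jul–Dec 2015, woman's age uniform over
15–49, weights constant or cluster-varying (uniform 0.5–1.5) — with
mutually consistent IR and BR layouts.  Fertility is a monthly Bernoulli
process with per-group probabilities f_a (defaults give ASFRs peaking at
~205 per 1000 in 20–24 and TFR* = 3.99), so ASFR*_a = 12000 f_a exactly.
Child survival follows stationary conditional segment hazards p*_i
(defaults at the level of a contemporary southern-African survey, U5MR*
≈ 69), with the death month uniform inside the segment and deaths after
the mother's interview censored to "surviving" — exactly the censoring the
synthetic-cohort estimator's survey-end convention is built for.  True
rates are ASFR*_a, TFR* = 5 Σ 12 f_a, and the five rates composed from p*.

The model deliberately omits parity dependence, birth spacing, union
dynamics, age- or period-varying child mortality, and date misreporting.
Passing recovery tests therefore demonstrates estimator correctness under
the stated sampling and censoring mechanisms, not robustness to the data
quality problems of real birth histories.

## Numerical and design choices

- All internal arithmetic is full precision; rounding (fertility 3 d.p.,
  mortality 2 d.p., probabilities 4 d.p., N/WN integers) happens only at
  display/serialization.
- Zero exposure in a group or segment yields a missing rate with a
  warning, not an error; inside jackknife replicates empty cells
  contribute zero so replicates never abort.
- The Monte-Carlo recovery study in the test suite uses 200 replicate
  surveys of the default design (1,000 women, ≈ 2,500 births each), sized
  to give stable coverage estimates while keeping the suite quick; the
  estimates must fall within 3 jackknife SEs of truth in ≥ 95% of
  replicates and the 95% TFR CI must cover truth 90–99% of the time.
- SPSS `.sav` reading requires the optional `pyreadstat` dependency; CSV
  and Stata `.dta` are supported natively.

## Known limitations

- Indirect (model-based) estimation, date imputation, sex-specific
  mortality and single-year ASFRs are out of scope.
- The N/WN reduction for multi-segment mortality rates is an approximation
  to unpublished tabulation conventions (above).
- The jackknife recomputes every replicate from scratch; for very large
  surveys with many clusters this is O(k) full tallies per indicator.
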