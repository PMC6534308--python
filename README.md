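# demorates

Direct estimation of fertility and childhood mortality rates from survey
birth histories, with complex-survey sampling errors.

In countries without complete vital registration, fertility and child
mortality are measured from retrospective birth histories collected by
household surveys (DHS, MICS and their relatives): each woman aged 15–49
reports the date of birth of every live-born child and, for deceased
children, the age at death.  `demorates` turns such woman-level (IR-shaped)
and birth-level (BR-shaped) tables into the standard occurrence/exposure
indicators, together with design-based standard errors for two-stage
stratified cluster samples.

## Indicators

**Fertility.** Over a reference window of calendar months (default: the 36
months before each woman's interview), for each five-year age group
*a* ∈ {15–19, …, 45–49}:

- ASFR_a = 1000 · B_a / E_a, with B_a the weighted births to women while in
  group *a* and E_a the weighted woman-years lived in group *a* inside the
  window (a woman's exposure can straddle two adjacent groups);
- TFR = 5 · Σ_a ASFR_a / 1000;
- GFR = 1000 · Σ_a B_a / (Σ_a E_a − E_45–49).

Ever-married samples are handled through all-women factors (`awfact*`),
percentages that inflate exposure — never births — so rates refer to all
women.

**Childhood mortality.** NNMR, PNMR, IMR, CMR and U5MR are built by the
synthetic-cohort life-table method: component death probabilities
p_i = D_i / N_i are computed for eight age segments (0, 1–2, 3–5, 6–11,
12–23, 24–35, 36–47, 48–59 completed months) over a window (default 60
months), where each segment's children split into three birth cohorts —
one fully exposed inside the window, two partially exposed edge cohorts
counting half the exposure and (in general) half the deaths.  The rates
combine segments multiplicatively, e.g.
U5MR = 1000 · (1 − Π_{i=1..8} (1 − p_i)) and PNMR = IMR − NNMR.

**Sampling errors.** ASFR and GFR are ratio estimators and get
Taylor-linearized SEs; TFR and the mortality rates get non-stratified
delete-one-cluster jackknife SEs.  Both come with the design effect (DEFT),
relative SE, and normal-theory confidence intervals.

All dates are century month codes (CMC = months since January 1900,
January 1900 = 1), the native coding of DHS/MICS recode files.

## Worked example

The package ships a generator for synthetic surveys in DHS recode format
with known true rates (here TFR* = 3.99, U5MR* ≈ 69 per 1000):

```python
from demorates import SimulationConfig, generate_survey
ir, br = generate_survey(SimulationConfig(), seed=7)
ir.to_csv("women.csv", index=False); br.to_csv("births.csv", index=False)
```

```
$ demorates fert women.csv --indicator tfr --jk
The current function calculated TFR based on a reference period of 36 months
The reference period ended at the time of the interview, in 2015.79 OR Jul—Dec 2015
The average reference period is 2014.29
  TFR   SE    N   WN  DEFT   RSE  LCI   UCI  iterations
3.873 0.18 2889 2799 0.804 0.046 3.52 4.225          40
```

The TFR estimate (3.873 children per woman) sits within one jackknife SE
(0.18) of the generator's true 3.99; N and WN are the unweighted and
weighted woman-years of exposure, and `iterations` is the number of
jackknife replicates (one per sample cluster).

```
$ demorates chmort births.csv --jk
The current function calculated Childhood Mortality Rates based on a reference period of 60 months
The reference period ended at the time of the interview, in 2015.79 OR Jul—Dec 2015
The average reference period is 2013.29
Rate     R   SE    N   WN  DEFT  RSE   LCI   UCI  iterations
NNMR 38.14 7.43  558  537  0.92 0.19 23.57 52.70          40
PNMR 26.42 6.51  628  604  1.02 0.25 13.66 39.18          40
 IMR 64.56 8.70  636  613  0.89 0.13 47.51 81.60          40
 CMR 17.44 4.90  940  900  1.15 0.28  7.84 27.04          40
U5MR 80.87 8.84 1098 1056  1.07 0.11 63.53 98.20          40
```

Rates are per 1000 live births; `demorates chmortp births.csv` prints the
underlying eight component probabilities with their weighted and
unweighted death/exposure tallies.  The same estimators are available as
library calls (`demorates.fert`, `demorates.chmort`, `demorates.chmortp`)
returning report objects with unrounded pandas tables.

Non-DHS surveys work by naming their columns, e.g. for a MICS women file:

```
demorates fert wm.csv --strata HH7 --cluster HH1 --weight wmweight \
    --date-of-interview WDOI --woman-dob WDOB --weight-divisor 1
```

and `demorates.birth_history_to_wide` attaches a separate birth-history
file as wide `b3_01..b3_20` columns.

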