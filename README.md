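# ckdproj

A Markov cohort model of chronic kidney disease (CKD) burden, detection,
and mortality in an adult population, built for epidemiologists and health
planners who need to project prevalence — including the *undiagnosed*
prevalence — decades ahead from partial disease-registry data.

## The model

The adult population is partitioned into nine mutually exclusive health
states: no CKD; stages 1-2, 3, and 4 each split into *undetected* and
*detected* compartments; stage 5 (end-stage renal disease, always detected
because renal-failure incidence is registered nationally); and death.
Cohort counts move once per one-year cycle under time-dependent transition
probabilities `P_ij(t)`. Progression is one-way (no regression), death is
absorbing, onset from the disease-free state goes either to stages 1-2
(with proteinuria) or directly to stage 3 (without), and progression flows
split between the destination's detected/undetected compartments by the
destination-stage detection probability.

Key identities the package implements:

* **Mortality decomposition.** Stage mortality is a relative risk times the
  background rate, `MR_it = RR_i · MR_t`, and the background rate is
  identified from the national death total:
  `MR_t = MV_t / (Σ_i RR_i · CKD_it + NCKD_t)`,
  so that re-expanding per-stage deaths reproduces `MV_t` exactly.
* **Detection probabilities.** A single detected-incident total closes the
  system through the assumption that detection-probability ratios between
  stages equal their mortality-rate ratios:
  `d_i = d_{1-2} · MR_i / MR_{1-2}`.
* **Registry coverage.** National counts are registry counts divided by the
  registry's coverage; stage-4 coverage (never observed directly) is the
  mean of the stage-3 and stage-5 coverages.
* **Ageing index.** Forecast probabilities for stages 1-4 are the 2010-2014
  base averages elevated by `m_t = 1 + e_t (e_t − ē)/ē`, where `e_t` is the
  elderly (65+) population share and `ē` its 2010-2014 mean; the stage 4→5
  progression is never elevated.

Because the registry-derived historical rate series behind the original
study are unpublished, the packaged forward rates are illustrative and a
synthetic registry generator (`ckdproj.synthetic`) provides ground-truth
validation for every estimator by parameter recovery.

## Worked example

```
python examples/base_year_burden.py
```

prints, from the packaged 2007 inputs:

```
2007 CKD cases by stage: 1-2: 145,803  3: 137,992  4: 24,293  5: 8,434
total CKD 316,522  prevalence 12.2%
undiagnosed prevalence 8.8% (stages 1-2: 4.8%)
proportion of CKD undiagnosed 72.1%, detection rate 27.9%
stage shares of CKD: stage 4 7.7%, stage 5 2.7%
```

Reading: the persistence-adjusted stages 1-2 prevalence (10.0% × 0.56 =
5.6%) times the 2,603,628 resident population gives 145,803 early-stage
cases; about one adult in eight has CKD, and 72.1% of them — mostly early
stage — are undiagnosed.

The other examples (`project_burden.py`, `sensitivity_scenarios.py`,
`uncertainty_bands.py`, `synthetic_recovery.py`) run the 28-cycle
projection, compounded incidence/detection scenarios, Monte-Carlo parameter
uncertainty, and estimator validation on a synthetic registry. A thin CLI
wraps the same calls:

```
ckdproj calibrate            # base-year burden
ckdproj project --seed 1     # full projection to CSV
ckdproj recover --seed 1     # synthetic-registry parameter recovery
```

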