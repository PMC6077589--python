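# Methods

## Model structure

The population aged 21+ is divided into nine mutually exclusive states:
no CKD; CKD stages 1-2, 3, and 4, each split into undetected and detected
compartments; CKD stage 5; and death. Counts are continuous expected
values (cohort simulation, not microsimulation) advanced by one-year
cycles: `n(t+1) = n(t) · P(t) + entrants(t)`, with entrants (net migrants
and live births) added after the transition flows and placed in the
disease-free state by default.

Structural assumptions:

* **One-way progression.** No regression to an earlier stage; individuals
  reside in a state for at least one cycle. This overstates late-stage
  counts where early CKD is in fact reversible.
* **Onset routes.** The disease-free state feeds stages 1-2 (onset with
  proteinuria) or stage 3 directly (onset without); all other progressions
  are to the adjacent stage. No other stage-skipping.
* **Detection.** A progression flow splits between the destination's
  detected and undetected compartments by the destination-stage detection
  probability. Stage-5 detection is identically 1 (renal-failure incidence
  is nationally registered). The legal-edge set also includes within-stage
  detection (undetected → detected at the same stage), off by default so
  the strictly progression-linked screening narrative is reproduced; a
  configuration flag (`within_stage_detection`) enables it, applying the
  stage's detection probability to non-progressors.
* **Competing death.** The model does not specify an order of death versus
  progression within a cycle. Each row's death entry equals the source
  state's mortality rate and the remaining flows (progression, detection,
  self-loop) are scaled by one minus it — simultaneous competing flows in
  one row-stochastic row. Stage 4's undetected and detected compartments
  progress to stage 5 at the same rate by default; they are independent
  parameters structurally.

## Base-year calibration (2007)

Stages 1-2 count = adjusted prevalence × population, where the adjustment
multiplies the single-measurement survey prevalence (10.0%) by the
persistence fraction of albuminuria (default 0.56, back-calculated from
the published 10.0% → 5.6% adjustment; kidney damage requires persistence
over 3 months). Stage 3 uses the raw survey prevalence (5.3%). Stages 4
and 5 use registry-coverage-derived national counts (defaults 24,293 and
8,434), because severe CKD is under-represented in surveys; the underlying
registry counts are unpublished, so the derived counts are accepted as
direct inputs while `national_count_from_coverage` remains available for
the full pipeline. Each stage splits into detected/undetected via the
detected fractions (stage 5 wholly detected); the rest of the population
is disease-free. Detected fractions derive from registry detected counts
under a 70% registry coverage of *detected* CKD, and clip at 1 with a
warning rather than failing, since sampling noise in a registry extract
can exceed national counts (coverage ratios clip the same way).

## Mortality

Annual probabilities throughout; no hazard↔probability conversion — the
arithmetic is one-year-cycle arithmetic. `MR_it = RR_i · MR_t` (capped at
1); given national deaths `MV_t`, the background rate solves
`MR_t = MV_t / (Σ RR_i · CKD_it + NCKD_t)`, an exact algebraic inverse of
the death decomposition. Historical relative risks are annual ratios
`MR_it / MR_t` averaged over 2010-2014 (averaging the annual ratios, not
re-pooling deaths). Forecast national adult deaths use a
stationary-population approximation — all-age deaths ≈ population / period
life expectancy, minus under-21 deaths — with every component overridable
by a direct series; the packaged default run instead interpolates a crude
death rate (6.5 → 10.0 per 1000 across the horizon) and multiplies by the
population path, because a young population's crude rate is far from its
stationary value and the base-year crude rate (6.50 per 1000) is a printed
input the default run should honour.

## Rate forecasting

Base probabilities are 2010-2014 arithmetic means of the annual series.
Forecast years elevate every stage 1-4 progression and detection
probability by the ageing multiplier `m_t = 1 + AI_t`, floored at 0 and
clipped at 1, with `AI_t = e_t · (e_t − ē)/ē`: the elderly share times its
*relative* increase from the 2010-2014 reference mean. The relative form
is the default because it is dimensionless; the absolute-difference
reading `AI_t = e_t · (e_t − ē)` is selectable (`ageing_form: absolute`).
The 4→5 progression is never elevated (competing risks of death dominate
among elderly stage-4 patients), and stage-5 detection stays 1.

Detection probabilities are identified from a single detected-incident
total by the ratio identity `d_i / d_{1-2} = MR_i / MR_{1-2}`, leaving one
linear unknown; solutions clip to [0, 1] with a warning. Historical
transition probabilities are estimated from registry counts as
coverage-corrected incident transitions divided by the survival-adjusted
start-of-year at-risk pool (exact-cohort estimator).

## Projection, scenarios, uncertainty

The default run covers 2007-2035 (29 snapshots, 28 cycles). Each cycle the
background mortality is solved from the year's national death total and
the *current* occupancy, the matrix is assembled and validated, the cohort
stepped, and entrants close the balance to a compounded population-growth
path (default 0.8%/yr). Conservation (alive + cumulative deaths −
cumulative entrants) is asserted every cycle at 1e-6 relative.

Scenarios multiply selected probabilities by `(1 + r)^(t − 2007)`.
Uncertainty uses independent mean-one log-normal multiplicative
perturbations per probability (default coefficient of variation 0.10),
re-running the projection per draw and reporting 2.5/50/97.5 percentiles;
draws failing matrix validation are rejected, redrawn, and counted. The
method models parameter uncertainty only, not stochastic cohort noise.
Rendered percentages round half-up to one decimal; full precision is kept
internally.

The packaged forward parameter set is **illustrative**: the
registry-derived historical probability series are unpublished, so 2035
levels produced by the default configuration demonstrate the machinery and
are not reproductions of published projections (which, with their
sensitivity deltas, therefore sit outside the reproducible surface; the
base-year 2007 figures are reproduced exactly).

## Synthetic registry

The generator emulates a chronic-disease registry with partial population
coverage observed over 2007-2014 against a million-person population:
coverage rising with severity (0.45 / 0.60 / imputed 0.725 / 0.85),
relative risks of death 1.5 / 2.5 / 5.0 / 10.0 (within and above the
reported stage 3-5 hazard-ratio range, stage 5 higher as dialysis
mortality is), background mortality 6.5 per 1000, 1%/yr population growth,
and detection probabilities on the ratio identity (0.15 / 0.25 / 0.50).
Noise: binomial thinning for coverage capture of prevalent counts, Poisson
for incident transition and detected-incident counts; per-stage death
counts carry Poisson event noise but no coverage thinning, because death
ascertainment is modelled as national death-registry linkage. The window
length and estimator pooling were set by an a-priori Poisson precision
calculation at the default population. All outputs are pure functions of
(truth, seed).

What the generator does *not* emulate: age/sex structure, stage 3A/3B
substructure, reversible early CKD, coverage drift over time, or
patient-level records. Passing recovery tests therefore show estimator
correctness and statistical efficiency under the stated noise model, not
robustness to those real-data features.

Recovery pipeline: coverage from 2007/2010 registry-vs-national ratios;
stage mortality from pooled deaths over pooled national pools; relative
risks from annual rate ratios (falling back to pooled ratios when a small
population yields a zero death count in some year); transition
probabilities from pooled coverage-corrected flows; detection
probabilities solved per year and averaged. With noise disabled the
inversion is exact to machine precision; at the default noise and
population, all eight probabilities are recovered within 5% relative error
in ≥95% of seeds.

## Numerical choices

* Transition-matrix validation: row sums within 1e-9, entries in [0, 1],
  structural zeros off the legal edge set exact.
* `step_cohort` is vectorised (`counts @ P`); tests check it against an
  explicit 81-pair accumulation oracle at 1e-12 relative.
* Tabular IO is comma-delimited text serialized at `%.17g` and parsed with
  round-trip float precision, so write-then-read is bit-exact.
* Degenerate inputs: zero probabilities assemble to the identity on alive
  states; an all-detected cohort reports zero undiagnosed burden; empty
  alive populations make the background-mortality solve fail loudly.

## Known limitations

Counts are expectations; no demographic stratification (the ageing index
is the sole ageing mechanism); the one-way progression assumption inflates
late-stage burden; the uncertainty method is a design choice (the original
interval method is unstated) and its defaults produce interval widths of
the same order as the published intervals only qualitatively; forward
rates in the packaged configuration are synthetic stand-ins.
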