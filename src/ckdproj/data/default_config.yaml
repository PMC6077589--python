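# Packaged default configuration: 2007 Singapore base-year inputs plus an
# illustrative forward parameter set.  The base-year block reproduces the
# published input table verbatim; the rates block is synthetic (the
# registry-derived historical series are unpublished) and is documented as
# illustrative in docs/methods.md.
base_year:
  year: 2007
  population: 2603628
  crude_mortality_per_1000: 6.50
  raw_prevalence:
    "1-2": 0.100
    "3": 0.053
    "4": 0.002
    "5": 0.0001
  persistence_fraction: 0.56
  undiagnosed:
    "1-2": 0.853
    "3": 0.669
    "4": 0.473
  stage4_count: 24293
  stage5_count: 8434

horizon:
  start: 2007
  end: 2035

rates:
  base_probabilities:
    p_non_12: 0.008
    p_non_3: 0.004
    p_12_3: 0.05
    p_3_4: 0.02
    p_4_5: 0.10
    d_12: 0.15
    d_3: 0.25
    d_4: 0.50
  rr:
    "1-2": 1.5
    "3": 2.5
    "4": 5.0
    "5": 10.0
  ageing_form: relative
  reference_window: [2010, 2014]
  elderly:
    start_year: 2007
    start_share: 0.085
    end_year: 2035
    end_share: 0.230
  within_stage_detection: false

mortality:
  # crude all-cause death rate per 1000, interpolated linearly across the
  # horizon; national death totals are this rate times the population path
  crude_rate_start_per_1000: 6.50
  crude_rate_end_per_1000: 10.0

population_growth: 0.008

scenario:
  incidence_change: {}
  detection_change: {}

uncertainty:
  n_draws: 200
  cv:
    p_non_12: 0.10
    p_non_3: 0.10
    p_12_3: 0.10
    p_3_4: 0.10
    p_4_5: 0.10
    d_12: 0.10
    d_3: 0.10
    d_4: 0.10

seed: 0
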