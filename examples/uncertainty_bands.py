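"""Monte-Carlo parameter uncertainty around the burden projection.

Each draw multiplies every progression and detection probability by an
independent mean-one log-normal factor (10% coefficient of variation) and
re-runs the projection; the 2.5/50/97.5 percentiles per year form the band.
"""

from ckdproj import load_configuration, monte_carlo_intervals

config = load_configuration()
cv, n_draws = config.uncertainty()
bands = monte_carlo_intervals(config.model_parameters(), cv, n_draws=n_draws,
                              seed=config.seed)

final = bands[bands["year"] == 2035].set_index("metric")
for metric in ("total_ckd", "prevalence"):
    row = final.loc[metric]
    print(f"2035 {metric}: {row['p50']:,.3g} "
          f"(95% interval {row['p2.5']:,.3g} - {row['p97.5']:,.3g})")
# The interval reflects parameter uncertainty only (no stochastic cohort
# noise): a 10% spread on annual rates compounds over 28 cycles into a
# materially wider spread on the 2035 burden.
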