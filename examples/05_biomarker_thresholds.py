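"""Extract biomarker thresholds from posterior-predictive odds curves.

For each metal the posterior predictive density of a new measurement is a
mixture of log-normals (one component per posterior draw).  The odds that
a new value belongs to the control group is the ratio of the two groups'
predictive densities; values beyond the points where the odds cross 10
(strong) or 100 (decisive) favor one group at that evidence grade.
"""

from bayeslod import (generate_panel, gibbs_fit, odds_curve,
                      study_scale_scenario, threshold_table)

asd, ctrl = study_scale_scenario("cord")
panel = generate_panel(asd, ctrl, "cord", seed=11)

d_asd, _ = gibbs_fit(panel.subset(group="ASD"), n_chains=2, n_iter=4000,
                     n_burnin=2000, seed=1)
d_ctl, _ = gibbs_fit(panel.subset(group="control"), n_chains=2, n_iter=4000,
                     n_burnin=2000, seed=2)

curve = odds_curve("Al", d_ctl, d_asd)
print(f"Al odds curve: O_control ranges {curve.odds_control.min():.2e} "
      f"to {curve.odds_control.max():.2e} over "
      f"[{curve.grid[0]:.2f}, {curve.grid[-1]:.2f}] {panel.unit}")

tab = threshold_table(d_ctl, d_asd, unit=panel.unit)
print(tab.to_frame().to_string(index=False))
print(f"note: {tab.caution}")
# a row "Al strong above x favored ASD" reads: a new individual with
# Al > x is at least 10 times more likely under the ASD predictive than
# under the control predictive.  A metal with no rows never reaches the
# cutoff anywhere (groups too similar), and a metal can have both a lower
# and an upper threshold when one group's spread is wider.
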