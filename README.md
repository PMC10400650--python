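# bayeslod

Bayesian group comparison of biomonitoring concentration panels in which
many values are reported only as "below the detection limit".

## The problem

Trace-element panels (here: Al, Cd, Hg, Li, Pb, Zn measured by ICP-SFMS
in cord blood at birth and in serum at age five, for children later
diagnosed with autism spectrum disorder versus controls) routinely have
30–60% of values left-censored at per-metal detection limits, plus
sporadic non-recorded values.  Discarding or substituting those values
biases every downstream comparison.  `bayeslod` instead models the full
vector of log-concentrations per individual as multivariate normal per
group,

    ln x ~ N(mu, Sigma),

and handles a censored cell through the conditional probability of its
censoring region given the observed cells,

    L_i = f(y1 | mu1, Sigma11) · F(y2 <= ln c | y1),

with non-recorded values treated as interval-censored on a plausibility
interval.  The posterior of (mu, Sigma) per group under a weakly
informative normal–inverse-Wishart prior is sampled by a
data-augmentation Gibbs sampler (truncated-normal imputation of censored
cells alternating with the exact conjugate update), gated on R-hat < 1.1
and effective sample size > 100 for every scalar parameter.

On top of the fits, the package computes:

- **Evidence-graded contrasts** — P(mean_ASD > mean_control) and the
  analogous SD and pairwise-correlation contrasts on the concentration
  scale, graded by the posterior odds K = P/(1−P): No (<3.2), Weak
  (3.2–10), Strong (10–100), Decisive (>100);
- **Stage ratios** — evidence that a metal's mean/SD rose between birth
  and age five, via the log-normal ratio X^(5)/X^(0);
- **LOOCV classification** — each individual's posterior-predictive
  probability of group membership under equiprobable priors, with
  strong (>0.909) and decisive (>0.990) favor rules and confusion
  matrices;
- **Biomarker thresholds** — concentrations where the ratio of the two
  groups' posterior-predictive densities crosses odds of 10 or 100, so
  more extreme values flag likely group membership.

## Worked example

```python
from bayeslod import (study_scale_scenario, generate_panel, gibbs_fit,
                      evidence_table)

asd, ctrl = study_scale_scenario("cord")   # n=20 / n=40, six metals
panel = generate_panel(asd, ctrl, "cord", seed=11)

d_asd, _ = gibbs_fit(panel.subset(group="ASD"), n_chains=2,
                     n_iter=4000, n_burnin=2000, seed=1)
d_ctl, _ = gibbs_fit(panel.subset(group="control"), n_chains=2,
                     n_iter=4000, n_burnin=2000, seed=2)
print(evidence_table(d_asd, d_ctl).to_string(index=False))
```

prints

```
metal  p_mean mean_favored mean_evidence  p_sd sd_favored sd_evidence
   Al   0.999          ASD           Dec 0.940        ASD         Str
   Cd   0.207      control            Wk 0.356    control          No
   Hg   0.840          ASD            Wk 0.786        ASD          Wk
   Li   0.716          ASD            No 0.711        ASD          No
   Pb   0.080      control           Str 0.123    control          Wk
   Zn   0.216      control            Wk 0.009    control         Dec
```

`p_mean` is the share of paired posterior draws in which the ASD group's
log-normal mean exceeds the control group's; 0.999 for Al is decisive
evidence (odds ≈ 1000) of a higher ASD mean — the generating scenario
shifts Al up by 0.30 log-units in the ASD group — and the decisive Zn SD
contrast recovers the control group's wider Zn spread.  At n = 20/40
with roughly 45% of cells censored, single panels are noisy: weak-grade
rows (like Cd's 0.207 here, generated with no group difference) come and
go across seeds, which is exactly why the evidence scale reserves
"strong" for odds above 10.  The `examples/`
directory has one short script per capability (panel IO, fitting,
evidence tables, LOOCV classification, thresholds, full pipeline), and
`bayeslod run --config cfg.yaml` drives the whole analysis from a YAML
file.

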