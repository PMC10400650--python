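# Methods

## Model

Each individual in a group contributes a vector of J analyte
concentrations x = (x_1, …, x_J).  The model assumes

    ln x ~ N(mu, Sigma)

per group, i.e. x is multivariate log-normal with per-metal mean
mu_xj = exp(mu_j + Sigma_jj/2) and covariance
Sigma_xjk = exp(mu_j + mu_k + (Sigma_jj + Sigma_kk)/2)(exp(Sigma_jk) − 1).

Biomonitoring panels measured by ICP-SFMS typically report many values
only as "below the detection limit c"; occasionally a value is simply
not recorded.  Writing y = ln x and partitioning y into observed (y1)
and censored (y2) parts, the per-individual likelihood is the marginal
normal density of y1 times the conditional probability that y2 falls in
its censoring region,

    L_i = f(y1 | mu1, Sigma11) · P(y2 ∈ R2 | y1),

where y2 | y1 is normal with mean mu2 + Sigma21 Sigma11⁻¹(y1 − mu1) and
covariance Sigma22 − Sigma21 Sigma11⁻¹ Sigma12.  For a below-limit cell
the region is (−∞, ln c]; a missing cell is interval-censored on a
plausibility interval [lower, upper) and contributes the conditional
probability of [ln lower, ln upper).  Both cases flow through the same
machinery; a missing cell is just a wider interval.

One-dimensional censored blocks use exact normal log-CDF arithmetic
(`log_ndtr`, with tail-safe `log1p` differencing); higher-dimensional
blocks use scipy's Genz quadrature for the multivariate normal CDF with
a pinned quadrature stream so results are reproducible.

## Prior and sampler

The prior on (mu, Sigma) is normal–inverse-Wishart:
mu | Sigma ~ N(m0, Sigma/kappa0), Sigma ~ IW(nu0, S0).  The weakly
informative default is derived from the panel itself: per metal, m0 is
the midpoint of the log-scale values (censored cells contribute their
log-limit, missing cells the midpoint of their finite log bounds),
S0 = diag((log-range/2)²), kappa0 = 0.01 and nu0 = J + 2.  At the group
sizes this package targets (n ≥ 11) the data dominate this prior; all
hyperparameters are overridable.

The posterior is sampled by data augmentation.  A Gibbs scan alternates:

1. **Latent imputation.**  For every censored/interval cell, a
   single-site truncated-normal update conditioning on all other
   coordinates of the same individual and the current (mu, Sigma).  The
   sweep is vectorized across individuals per coordinate.  Truncated
   normals are drawn by inverse CDF evaluated on log-probabilities
   (`log_ndtr` / `ndtri_exp` after reflecting the interval into the lower
   tail), which is exact arbitrarily far into the tail — no rejection
   step, no underflow.
2. **Conjugate update.**  Given the completed log-data, (mu, Sigma) is
   drawn from the exact normal–inverse-Wishart conditional.

Defaults are 4 chains of 10,000 scans with 5,000 burn-in and no
thinning; chains start from overdispersed latent initializations.  Every
fit computes R-hat and effective sample size per scalar parameter
(mu_j and the upper triangle of Sigma), delegating to ArviZ's
rank-normalized split estimators, and the pipeline refuses to summarize
any fit that does not meet R-hat < 1.1 and ESS > 100 for all parameters.
Fully observed data skip step 1, making the retained draws iid from the
closed-form conjugate posterior — the basis of the sampler's strongest
oracle test.

## Evidence grading

All group contrasts are computed draw-by-draw on log-normal-scale
functionals: means, SDs, and pairwise correlations derived from the
log-normal covariance (a log-scale alternative is available behind the
`scale="log"` flag).  For two independently fitted groups, draws are
paired by index after truncation to the common length; when the two draw
lists are physically identical (self-comparison in tests) a cyclic shift
of one list avoids comparing a draw with itself.  Any exchangeable
pairing estimates the same probability for independent posteriors.

A contrast probability P is graded by the posterior odds K = P/(1 − P):
No (< 3.2), Weak (3.2–10), Strong (10–100), Decisive (> 100).  The
probability edges are used at the conventional printed precision
0.762 / 0.909 / 0.990 (each equals K/(1+K) to three decimals), with
P ≥ 0.990 grading as decisive.

Stage comparisons (cord blood at birth versus serum at age five) use the
ratio R = X^(5)/X^(0) of independent log-normals, which is log-normal
with log-mean mu5_j − mu0_j and log-variance Sigma5_jj + Sigma0_jj per
paired draw; reported are P(mean of R > 1) and P(SD of R > 1).

## Classification

Each individual i is scored by leave-one-out cross-validation: both
group models are fitted to all data except i (the other group's training
data never contains i, so its full-data fit already is the leave-one-out
fit and is reused).  The record's posterior-predictive likelihood under
each group — censored cells scored through the censored likelihood, not
imputed — is evaluated per posterior draw, and with equiprobable class
priors the per-draw membership probability is
p = L_ASD/(L_ASD + L_control), so the per-draw odds of control equal the
likelihood ratio exactly.  The draw-averaged probability is compared to
0.909 (strong) or 0.990 (decisive); individuals exceeding neither bound
for either group are reported as not classified.  A fast mode scoring
everyone against the two full-data fits exists for smoke tests only; it
trains on the held-out point and is labelled non-canonical.

## Predictive thresholds

The marginal posterior predictive of one metal is the equal-weight
mixture of log-normal densities over posterior draws (Rao-Blackwellized;
no kernel smoothing).  The odds that a new value belongs to the control
group is the ratio of the two groups' predictive densities, evaluated in
log space on 2,000 log-spaced grid points spanning the pooled
0.001–0.999 predictive envelope (the envelope takes the extreme
per-component quantiles, so the grid covers at least the central 99% of
both predictives).  Crossings of the odds with 10 (strong) and 100
(decisive) — located by linear interpolation in (log x, log odds) — are
reported as thresholds, labelled by the group favored beyond them.  A
metal may produce no thresholds, one, or a lower and an upper one
(non-monotone odds, e.g. when one group's spread is much wider).
Thresholds live in predictive tails, which are sensitive to outliers in
small panels; every threshold table carries that caution.

## Synthetic data

The generator draws each individual as exp of a multivariate normal,
censors components below per-metal detection limits, and knocks out
cells completely at random (default rate 0.02, matching a panel with
only sporadic non-recorded values) as interval-censored missingness on
[0, 10 × largest observed value of the metal].  The study-scale
scenarios use the target design's sizes (n=20/40 cord, n=11/24 at five
years), six metals (Al, Cd, Hg, Li, Pb, Zn), order-of-magnitude
plausible ug/L levels, qualitative group contrasts (ASD higher in Al and
Hg, wider Al/Li spread; control wider in Pb/Zn with a strong Pb–Al
correlation), and detection limits at the 44% quantile of the pooled
log-normal per metal, which puts every metal's analytic censoring
fraction inside 30–60% for both groups.

What the generator does *not* emulate: batch-varying detection limits
(supported by the data model, not generated), non-log-normal tails,
informative missingness, covariates, and measurement error beyond the
log-normal spread.  Passing tests therefore demonstrate correctness of
the inferential machinery under the model's own assumptions, not that
real cord-blood panels satisfy those assumptions.

## Numerical and design choices

- Missingness is completely at random; nothing in the study design
  identifies a mechanism.
- Interval cells are handled as two-sided truncation inside the same
  latent sweep as detection-limit cells.
- Per-cell detection limits are supported (limits may differ between
  individuals); batch-dependent limits are common in practice.
- Degenerate conditional variances in the sweep are floored at 1e-12;
  rectangle probabilities are floored at 1e-300 before taking logs.
- Density ratios and predictive densities are computed in log space with
  max-shifted log-sum-exp.
- The master seed spawns deterministic substreams per pipeline stage
  (each fit, the LOOCV refits, predictive grids); reruns are
  byte-identical, and the randomized multivariate-normal-CDF quadrature
  uses a pinned stream.
- Problem sizes in the shipped checks are chosen to keep the full
  verification run in the tens of minutes on one core: the conjugate
  oracle uses 20,000 retained draws; interval-coverage uses 100
  replicate fits at 2,500 scans each; the null-calibration of the
  classifier averages 10 study-scale panels in fast LOOCV mode with 150
  paired draws per individual.

## Limitations

- Single-site truncated-normal sweeps mix slowly if censored coordinates
  are extremely correlated; at J=6 and the observed correlation levels
  the convergence gate is met comfortably, but pathological Sigma could
  require longer chains (the gate will say so rather than pass).
- K = 1 mixture component per group: no multimodality, no covariates,
  no replicate measurements.
- No multiplicity adjustment across metals or metal pairs is applied, by
  design of the analysis this package reproduces.
- Threshold units are whatever unit label the panel carries; no unit
  conversion is attempted.
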