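"""Leave-one-out posterior-predictive classification of individuals.

Each individual i is scored by the two group models fitted without i:
the posterior-predictive likelihood of i's record (censored cells scored
through the censored likelihood, never imputed first) is averaged over
posterior draws for each group, and under equiprobable class priors the
probability of ASD membership per paired draw (mu, Sigma) is

    p_i = L_ASD / (L_ASD + L_control),

so the per-draw odds of being a control equal the likelihood ratio.
Individuals whose draw-averaged probability exceeds 0.909 (strong) or
0.990 (decisive) for either group are classified; the rest are reported
as not classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .gibbs import (PosteriorDraws, PriorSpec, _cells_to_arrays,
                    _record_loglik_arrays, gibbs_fit)
from .panel import MetalPanel

__all__ = [
    "McmcConfig",
    "ClassProbability",
    "ConfusionMatrix",
    "FAVOR_THRESHOLDS",
    "log_predictive_density",
    "predictive_density",
    "loocv_probabilities",
    "apply_favor_rule",
    "classification_frame",
]

#: draw-averaged probability an individual must exceed (for either group)
#: to be classified; the values are the evidence-scale bin edges 10/11 and
#: 100/101
FAVOR_THRESHOLDS = {"strong": 10 / 11, "decisive": 100 / 101}


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_iter: int = 10_000
    n_burnin: int = 5_000
    n_thin: int = 1


def _record_logliks(cells, draws: PosteriorDraws) -> np.ndarray:
    status, lo, hi = _cells_to_arrays(cells)
    return np.array([_record_loglik_arrays(draws.mu[t], draws.sigma[t], status, lo, hi)
                     for t in range(len(draws))])


def log_predictive_density(cells, draws: PosteriorDraws) -> float:
    """Log of the Monte-Carlo posterior-predictive density of one record:
    log mean_t exp(loglik_t), computed with a max-shift for stability."""
    if len(draws) == 0:
        raise ValueError("empty draw set")
    ll = _record_logliks(cells, draws)
    return float(logsumexp(ll) - np.log(len(ll)))


def predictive_density(cells, draws: PosteriorDraws) -> float:
    return float(np.exp(log_predictive_density(cells, draws)))


@dataclass
class ClassProbability:
    """Posterior distribution of one individual's ASD-membership probability."""

    id: str
    actual: str
    prob_draws: np.ndarray  # per paired draw, p(C = ASD)
    mean_prob: float = field(init=False)

    def __post_init__(self) -> None:
        self.prob_draws = np.asarray(self.prob_draws, dtype=float)
        if np.any((self.prob_draws < 0) | (self.prob_draws > 1)):
            raise ValueError("class probabilities must lie in [0, 1]")
        self.mean_prob = float(self.prob_draws.mean())

    def favored(self, level: str = "strong") -> str:
        thr = FAVOR_THRESHOLDS[level]
        if self.mean_prob > thr:
            return "ASD"
        if 1.0 - self.mean_prob > thr:
            return "control"
        return "unclassified"

    def quantiles(self, qs=(0.025, 0.975)) -> np.ndarray:
        return np.quantile(self.prob_draws, qs)


def loocv_probabilities(panel: MetalPanel, prior: PriorSpec | None = None,
                        mcmc: McmcConfig | None = None, seed: int = 0,
                        n_pair_draws: int | None = None,
                        exact: bool = True) -> list[ClassProbability]:
    """LOOCV class probabilities for every individual of a two-group panel.

    ``exact=True`` refits the held-out individual's own group without that
    individual for each i (the other group's training data never contains
    i, so its full-data fit is already the leave-one-out fit).
    ``exact=False`` is a fast smoke-test mode that scores everyone against
    the two full-data fits; it is *not* leave-one-out and mildly favors
    the individual's own group.
    """
    mcmc = mcmc or McmcConfig()
    groups = ("ASD", "control")
    sizes = {g: int(np.sum(panel.group == g)) for g in groups}
    for g, ng in sizes.items():
        if ng < 3:
            raise ValueError(f"group {g!r} has {ng} members; LOOCV needs at least 3")

    ss = np.random.SeedSequence(seed)
    full_seeds = dict(zip(groups, ss.spawn(2)))
    loo_ss = ss.spawn(panel.n)

    def _fit(sub: MetalPanel, s: np.random.SeedSequence) -> PosteriorDraws:
        d, _ = gibbs_fit(sub, prior=prior, n_chains=mcmc.n_chains, n_iter=mcmc.n_iter,
                         n_burnin=mcmc.n_burnin, n_thin=mcmc.n_thin,
                         seed=int(s.generate_state(1)[0] % (2 ** 31)))
        return d

    full = {g: _fit(panel.subset(group=g), full_seeds[g]) for g in groups}

    results = []
    for i in range(panel.n):
        g_own = panel.group[i]
        if exact:
            own = _fit(panel.subset(group=g_own, drop_index=i), loo_ss[i])
        else:
            own = full[g_own]
        models = {g: (own if g == g_own else full[g]) for g in groups}
        if n_pair_draws is not None:
            models = {g: d.subsample(n_pair_draws) for g, d in models.items()}
        m = min(len(models["ASD"]), len(models["control"]))
        cells = panel.row_cells(i)
        ll_asd = _record_logliks(cells, models["ASD"])[:m]
        ll_ctl = _record_logliks(cells, models["control"])[:m]
        # p = L_A / (L_A + L_C) per paired draw, in log space
        probs = 1.0 / (1.0 + np.exp(np.clip(ll_ctl - ll_asd, -700, 700)))
        results.append(ClassProbability(id=panel.ids[i], actual=str(g_own), prob_draws=probs))
    return results


@dataclass
class ConfusionMatrix:
    """Actual group x (predicted control, predicted ASD, not classified)."""

    level: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        expected_cols = ["predicted_control", "predicted_ASD", "not_classified"]
        if list(self.counts.columns) != expected_cols:
            raise ValueError(f"counts must have columns {expected_cols}")

    @property
    def n_classified(self) -> int:
        return int(self.counts[["predicted_control", "predicted_ASD"]].to_numpy().sum())

    @property
    def n_correct(self) -> int:
        return int(self.counts.loc["control", "predicted_control"]
                   + self.counts.loc["ASD", "predicted_ASD"])

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["total"] = out.sum(axis=1)
        return out


def apply_favor_rule(results: list[ClassProbability], level: str = "strong") -> ConfusionMatrix:
    """Confusion matrix at the strong (0.909) or decisive (0.990) rule."""
    if not results:
        raise ValueError("no classification results")
    if level not in FAVOR_THRESHOLDS:
        raise ValueError(f"level must be one of {sorted(FAVOR_THRESHOLDS)}")
    counts = pd.DataFrame(0, index=["control", "ASD"],
                          columns=["predicted_control", "predicted_ASD", "not_classified"])
    for r in results:
        fav = r.favored(level)
        col = {"control": "predicted_control", "ASD": "predicted_ASD",
               "unclassified": "not_classified"}[fav]
        counts.loc[r.actual, col] += 1
    return ConfusionMatrix(level=level, counts=counts)


def classification_frame(results: list[ClassProbability]) -> pd.DataFrame:
    """Per-individual summary: mean probability, central interval, favor."""
    rows = []
    for r in results:
        q = r.quantiles()
        rows.append({"id": r.id, "actual": r.actual,
                     "mean_prob_ASD": r.mean_prob,
                     "q2.5": q[0], "q97.5": q[1],
                     "favored_strong": r.favored("strong"),
                     "favored_decisive": r.favored("decisive")})
    return pd.DataFrame(rows)
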