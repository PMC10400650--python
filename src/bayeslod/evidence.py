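"""Group contrasts on the log-normal scale, posterior odds, evidence labels.

All comparisons are made draw-by-draw on functionals of the log-normal
concentration distribution implied by each posterior draw (mu, Sigma):
the per-metal mean mu_x = exp(mu_j + Sigma_jj / 2), the per-metal SD
derived from the log-normal variance, and pairwise correlations derived
from the log-normal covariance.  A contrast probability P (say,
P(mean_A > mean_C)) is the fraction of paired posterior draws in which
the functional is larger for one group; the posterior odds K = P / (1 - P)
are graded on a four-step evidence scale:

====================  ===========  ==================
K                     P            label
====================  ===========  ==================
1 to 3.2              0.5-0.762    No (bare mention)
3.2 to 10             0.762-0.909  Wk (weak)
10 to 100             0.909-0.990  Str (strong)
> 100                 > 0.990      Dec (decisive)
====================  ===========  ==================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import PosteriorDraws

__all__ = [
    "lognormal_mean",
    "lognormal_cov",
    "lognormal_sd",
    "LogNormalDrawSummary",
    "lognormal_summaries",
    "posterior_odds",
    "evidence_label",
    "EvidenceResult",
    "contrast_probability",
    "RatioContrast",
    "stage_ratio_contrast",
    "evidence_table",
    "correlation_table",
    "ratio_table",
    "EVIDENCE_BINS",
]

#: probability bin edges of the evidence scale, at the conventional printed
#: precision; each equals K / (1 + K) to 3 decimals for the odds cutoffs
#: K = 3.2, 10, 100, and a probability at or above 0.990 grades as decisive
EVIDENCE_BINS = {"Wk": 0.762, "Str": 0.909, "Dec": 0.990}
_LABELS = ("No", "Wk", "Str", "Dec")


def lognormal_mean(mu_j: float, sigma_jj: float):
    """Mean of a log-normal: exp(mu_j + Sigma_jj / 2)."""
    return np.exp(np.asarray(mu_j) + 0.5 * np.asarray(sigma_jj))


def lognormal_cov(mu_j, mu_k, sigma_jj, sigma_kk, sigma_jk):
    """Covariance of log-normal components j and k:
    exp(mu_j + mu_k + (Sigma_jj + Sigma_kk) / 2) (exp(Sigma_jk) - 1)."""
    return np.exp(np.asarray(mu_j) + np.asarray(mu_k)
                  + 0.5 * (np.asarray(sigma_jj) + np.asarray(sigma_kk))) \
        * np.expm1(np.asarray(sigma_jk))


def lognormal_sd(mu_j, sigma_jj):
    return np.sqrt(lognormal_cov(mu_j, mu_j, sigma_jj, sigma_jj, sigma_jj))


@dataclass
class LogNormalDrawSummary:
    """Per-draw log-normal-scale functionals: means, SDs, correlations."""

    metals: list[str]
    mu_x: np.ndarray  # (m, J)
    sigma_x: np.ndarray  # (m, J)
    rho: np.ndarray  # (m, J, J), unit diagonal


def lognormal_summaries(draws: PosteriorDraws, scale: str = "lognormal") -> LogNormalDrawSummary:
    """Map (mu, Sigma) draws to concentration-scale summaries.

    ``scale='lognormal'`` derives correlations from the log-normal
    covariance matrix of x; ``scale='log'`` uses the normal-scale
    correlations of ln x instead.
    """
    mu, S = draws.mu, draws.sigma
    d = np.einsum("tjj->tj", S)  # (m, J) log-scale variances
    mu_x = np.exp(mu + 0.5 * d)
    var_x = np.exp(2 * mu + 2 * d) - np.exp(2 * mu + d)
    sigma_x = np.sqrt(var_x)
    if scale == "lognormal":
        cov_x = np.exp(mu[:, :, None] + mu[:, None, :]
                       + 0.5 * (d[:, :, None] + d[:, None, :])) * np.expm1(S)
        sd = np.sqrt(np.einsum("tjj->tj", cov_x))
        rho = cov_x / (sd[:, :, None] * sd[:, None, :])
    elif scale == "log":
        sd = np.sqrt(d)
        rho = S / (sd[:, :, None] * sd[:, None, :])
    else:
        raise ValueError("scale must be 'lognormal' or 'log'")
    for t in range(rho.shape[0]):
        np.fill_diagonal(rho[t], 1.0)
    return LogNormalDrawSummary(list(draws.metals), mu_x, sigma_x, rho)


def posterior_odds(p: float) -> float:
    """Posterior odds K = p / (1 - p); returns inf at p = 1 and 0 at p = 0."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p == 1.0:
        return math.inf
    return p / (1.0 - p)


def evidence_label(p: float) -> str:
    """Evidence grade for the favored direction, evaluated on max(p, 1-p)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    q = max(p, 1.0 - p)
    if q < EVIDENCE_BINS["Wk"]:
        return "No"
    if q < EVIDENCE_BINS["Str"]:
        return "Wk"
    if q < EVIDENCE_BINS["Dec"]:
        return "Str"
    return "Dec"


@dataclass
class EvidenceResult:
    """A graded group contrast.

    ``p`` is the posterior probability that the functional is larger in
    the favored group (always >= 0.5); ``p_a_gt_b`` keeps the raw
    direction (first argument larger).
    """

    p: float
    k: float
    label: str
    favored: str
    p_a_gt_b: float

    def formatted(self) -> str:
        """Table-style presentation: raw p, or 1-p when the second group is favored."""
        return f"{self.p_a_gt_b:.3f}" if self.p_a_gt_b >= 0.5 else f"1-{self.p:.3f}"


def _functional_series(draws: PosteriorDraws, functional: str, metal=None, pair=None,
                       scale: str = "lognormal") -> np.ndarray:
    summ = lognormal_summaries(draws, scale=scale)
    if functional in ("mean", "sd"):
        if metal is None:
            raise ValueError("metal required for mean/sd contrasts")
        j = summ.metals.index(metal) if isinstance(metal, str) else int(metal)
        return (summ.mu_x if functional == "mean" else summ.sigma_x)[:, j]
    if functional == "correlation":
        if pair is None:
            raise ValueError("pair required for correlation contrasts")
        j, k = (summ.metals.index(m) if isinstance(m, str) else int(m) for m in pair)
        if j == k:
            raise ValueError("correlation contrast requires two distinct metals")
        return summ.rho[:, j, k]
    raise ValueError(f"unknown functional {functional!r}")


def _paired(fa: np.ndarray, fb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = min(len(fa), len(fb))
    fa, fb = fa[:m], fb[:m]
    if np.array_equal(fa, fb):
        # physically identical draw lists: cyclic shift avoids comparing a
        # draw with itself, which would degenerate to P = 0 ties
        fb = np.roll(fb, 1)
    return fa, fb


def contrast_probability(draws_a: PosteriorDraws, draws_b: PosteriorDraws,
                         functional: str, metal=None, pair=None,
                         labels: tuple[str, str] = ("ASD", "control"),
                         scale: str = "lognormal") -> EvidenceResult:
    """P(functional_A > functional_B) over index-paired posterior draws.

    The two fits are independent, so any exchangeable pairing of their
    draw lists estimates the same probability; draws are paired by index
    after truncation to the common length.
    """
    fa = _functional_series(draws_a, functional, metal, pair, scale)
    fb = _functional_series(draws_b, functional, metal, pair, scale)
    fa, fb = _paired(fa, fb)
    p_ab = float(np.mean(fa > fb))
    p = max(p_ab, 1.0 - p_ab)
    return EvidenceResult(p=p, k=posterior_odds(p), label=evidence_label(p),
                          favored=labels[0] if p_ab >= 0.5 else labels[1],
                          p_a_gt_b=p_ab)


@dataclass
class RatioContrast:
    """Evidence that a metal's level rose between two sampling stages.

    For paired draws of two independent stage fits, the ratio
    R = X_stage1 / X_stage0 of independent log-normals is log-normal with
    log-scale mean mu1_j - mu0_j and variance Sigma1_jj + Sigma0_jj; the
    probabilities refer to the mean and SD of R exceeding 1.
    """

    metal: str
    p_mean_gt_1: float
    p_sd_gt_1: float
    label_mean: str
    label_sd: str


def stage_ratio_contrast(draws_stage0: PosteriorDraws, draws_stage1: PosteriorDraws,
                         metal) -> RatioContrast:
    if list(draws_stage0.metals) != list(draws_stage1.metals):
        raise ValueError("stage fits cover different metal panels")
    j = draws_stage0.metals.index(metal) if isinstance(metal, str) else int(metal)
    name = draws_stage0.metals[j]
    m0, m1 = draws_stage0.mu[:, j], draws_stage1.mu[:, j]
    v0 = draws_stage0.sigma[:, j, j]
    v1 = draws_stage1.sigma[:, j, j]
    n = min(len(m0), len(m1))
    lm = m1[:n] - m0[:n]
    lv = v1[:n] + v0[:n]
    mean_r = np.exp(lm + 0.5 * lv)
    sd_r = np.sqrt(np.expm1(lv)) * mean_r
    p_mean = float(np.mean(mean_r > 1.0))
    p_sd = float(np.mean(sd_r > 1.0))
    return RatioContrast(metal=name, p_mean_gt_1=p_mean, p_sd_gt_1=p_sd,
                         label_mean=evidence_label(p_mean), label_sd=evidence_label(p_sd))


# ----------------------------------------------------------------------
# table builders
# ----------------------------------------------------------------------

def evidence_table(draws_a: PosteriorDraws, draws_b: PosteriorDraws,
                   labels: tuple[str, str] = ("ASD", "control")) -> pd.DataFrame:
    """Per-metal mean and SD contrasts (probability, direction, grade)."""
    rows = []
    for metal in draws_a.metals:
        r_mean = contrast_probability(draws_a, draws_b, "mean", metal=metal, labels=labels)
        r_sd = contrast_probability(draws_a, draws_b, "sd", metal=metal, labels=labels)
        rows.append({"metal": metal,
                     "p_mean": round(r_mean.p_a_gt_b, 3), "mean_favored": r_mean.favored,
                     "mean_evidence": r_mean.label,
                     "p_sd": round(r_sd.p_a_gt_b, 3), "sd_favored": r_sd.favored,
                     "sd_evidence": r_sd.label})
    return pd.DataFrame(rows)


def correlation_table(draws_a: PosteriorDraws, draws_b: PosteriorDraws,
                      labels: tuple[str, str] = ("ASD", "control")) -> pd.DataFrame:
    """All pairwise correlation contrasts (upper triangle of the metal grid)."""
    rows = []
    metals = draws_a.metals
    for j in range(len(metals)):
        for k in range(j + 1, len(metals)):
            r = contrast_probability(draws_a, draws_b, "correlation",
                                     pair=(metals[j], metals[k]), labels=labels)
            rows.append({"metal_1": metals[j], "metal_2": metals[k],
                         "p_rho": round(r.p_a_gt_b, 3), "favored": r.favored,
                         "evidence": r.label})
    return pd.DataFrame(rows)


def ratio_table(draws_stage0: PosteriorDraws, draws_stage1: PosteriorDraws,
                group: str) -> pd.DataFrame:
    """Stage-ratio contrasts for every metal of one group."""
    rows = []
    for metal in draws_stage0.metals:
        r = stage_ratio_contrast(draws_stage0, draws_stage1, metal)
        rows.append({"group": group, "metal": r.metal,
                     "p_mean_ratio_gt_1": round(r.p_mean_gt_1, 3), "mean_evidence": r.label_mean,
                     "p_sd_ratio_gt_1": round(r.p_sd_gt_1, 3), "sd_evidence": r.label_sd})
    return pd.DataFrame(rows)
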