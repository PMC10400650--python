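"""Posterior predictive distributions, group odds curves, biomarker thresholds.

The posterior predictive density of a new metal value is the posterior
average of the log-normal density with that draw's (mu_j, Sigma_jj) — a
Rao-Blackwellized mixture that is exact given the draws, with no kernel
smoothing.  The odds that a new value x belongs to the control group,

    O_control(x) = p(x | data, control) / p(x | data, ASD),

is the ratio of the two groups' marginal predictive densities.  Grid
points where the odds cross 10 (strong) or 100 (decisive) — in either
direction — are extracted as candidate biomarker thresholds: a value more
extreme than the threshold favors one group at that evidence grade.

Thresholds live in the tails of the predictive distributions; with small
panels the tails are sensitive to outliers, so every threshold table
carries a caution note to that effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from .gibbs import PosteriorDraws

__all__ = [
    "predictive_draws",
    "MarginalPredictive",
    "marginal_predictive_density",
    "OddsCurve",
    "odds_curve",
    "ThresholdRow",
    "ThresholdTable",
    "find_thresholds",
    "threshold_table",
    "ODDS_LEVELS",
    "TAIL_CAUTION",
]

ODDS_LEVELS = {"strong": 10.0, "decisive": 100.0}
TAIL_CAUTION = ("thresholds sit in predictive tails, which are sensitive to "
                "outliers in small panels; interpret with caution")


def predictive_draws(draws: PosteriorDraws, m: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate m new individuals' concentration vectors.

    Each row picks a posterior (mu, Sigma) uniformly at random, draws
    ln x ~ N(mu, Sigma) and exponentiates.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    J = draws.J
    out = np.empty((m, J))
    chol = np.linalg.cholesky(draws.sigma)  # (n_draws, J, J)
    for start in range(0, m, 100_000):
        stop = min(start + 100_000, m)
        idx = rng.integers(0, len(draws), size=stop - start)
        z = rng.standard_normal((stop - start, J))
        out[start:stop] = np.exp(draws.mu[idx] + np.einsum("tjk,tk->tj", chol[idx], z))
    return out


@dataclass
class MarginalPredictive:
    """Marginal posterior predictive of one metal: an equal-weight mixture
    of log-normals, one component per posterior draw."""

    metal: str
    mu: np.ndarray  # (n_draws,) log-scale means
    sd: np.ndarray  # (n_draws,) log-scale SDs

    def logpdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(x <= 0):
            raise ValueError("predictive density is defined on (0, inf)")
        lx = np.log(x)
        out = np.empty(x.shape)
        for start in range(0, x.size, 256):  # chunk the (draws x grid) matrix
            sl = slice(start, min(start + 256, x.size))
            z = (lx[sl][None, :] - self.mu[:, None]) / self.sd[:, None]
            comp = -0.5 * z ** 2 - np.log(self.sd[:, None]) - 0.5 * np.log(2 * np.pi) \
                - lx[sl][None, :]
            out[sl] = logsumexp(comp, axis=0) - np.log(len(self.mu))
        return out

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def cdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(x <= 0):
            raise ValueError("predictive CDF is defined on (0, inf)")
        lx = np.log(x)
        z = (lx[None, :] - self.mu[:, None]) / self.sd[:, None]
        return ndtr(z).mean(axis=0)

    def quantile_envelope(self, q_lo: float, q_hi: float) -> tuple[float, float]:
        """Conservative bracket of the central mass: the extreme per-draw
        log-normal quantiles over all mixture components."""
        from scipy.stats import norm
        z_lo, z_hi = norm.ppf(q_lo), norm.ppf(q_hi)
        return (float(np.exp(np.min(self.mu + z_lo * self.sd))),
                float(np.exp(np.max(self.mu + z_hi * self.sd))))


def marginal_predictive_density(metal, draws: PosteriorDraws,
                                min_draws: int = 100) -> MarginalPredictive:
    if len(draws) < min_draws:
        raise ValueError(f"need at least {min_draws} posterior draws, got {len(draws)}")
    j = draws.metals.index(metal) if isinstance(metal, str) else int(metal)
    return MarginalPredictive(metal=draws.metals[j], mu=draws.mu[:, j],
                              sd=np.sqrt(draws.sigma[:, j, j]))


@dataclass
class OddsCurve:
    """O_control over a concentration grid (log-odds kept for precision)."""

    metal: str
    grid: np.ndarray  # strictly increasing positive concentrations
    log_odds_control: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0) or np.any(self.grid <= 0):
            raise ValueError("grid must be strictly increasing and positive")
        if not np.all(np.isfinite(self.log_odds_control)):
            raise ValueError("log odds must be finite on the evaluated grid")

    @property
    def odds_control(self) -> np.ndarray:
        return np.exp(self.log_odds_control)

    @property
    def odds_asd(self) -> np.ndarray:
        return np.exp(-self.log_odds_control)


def odds_curve(metal, draws_control: PosteriorDraws, draws_asd: PosteriorDraws,
               n_grid: int = 2000, q_lo: float = 0.001, q_hi: float = 0.999) -> OddsCurve:
    """Control-vs-ASD predictive odds on a log-spaced grid spanning the
    pooled (q_lo, q_hi) predictive envelope of both groups.

    Grid points where either density underflows to zero are dropped with
    a warning.
    """
    pc = marginal_predictive_density(metal, draws_control)
    pa = marginal_predictive_density(metal, draws_asd)
    lo_c, hi_c = pc.quantile_envelope(q_lo, q_hi)
    lo_a, hi_a = pa.quantile_envelope(q_lo, q_hi)
    grid = np.exp(np.linspace(np.log(min(lo_c, lo_a)), np.log(max(hi_c, hi_a)), n_grid))
    log_odds = pc.logpdf(grid) - pa.logpdf(grid)
    ok = np.isfinite(log_odds)
    if not ok.all():
        warnings.warn(f"{metal}: dropped {int((~ok).sum())} grid points where a "
                      "predictive density underflowed")
    return OddsCurve(metal=pc.metal, grid=grid[ok], log_odds_control=log_odds[ok])


@dataclass
class ThresholdRow:
    metal: str
    level: str  # strong / decisive
    threshold: float
    side: str  # "below" / "above": which side of the threshold is more extreme
    favored: str  # group favored beyond the threshold


@dataclass
class ThresholdTable:
    rows: list[ThresholdRow]
    caution: str = TAIL_CAUTION
    unit: str = ""

    def to_frame(self) -> pd.DataFrame:
        if not self.rows:
            return pd.DataFrame(columns=["metal", "level", "threshold", "side", "favored"])
        return pd.DataFrame([vars(r) for r in self.rows])

    def for_metal(self, metal: str, level: str) -> list[ThresholdRow]:
        return [r for r in self.rows if r.metal == metal and r.level == level]


def _crossings(x: np.ndarray, y: np.ndarray, c: float) -> list[float]:
    """x-locations where the piecewise-linear y(log x) crosses level c."""
    out = []
    lx = np.log(x)
    above = y >= c
    for i in np.where(above[1:] != above[:-1])[0]:
        t = (c - y[i]) / (y[i + 1] - y[i])
        out.append(float(np.exp(lx[i] + t * (lx[i + 1] - lx[i]))))
    return out


def find_thresholds(curve: OddsCurve, levels: dict[str, float] | None = None,
                    unit: str = "") -> ThresholdTable:
    """Extract evidence thresholds from an odds curve.

    For each odds cutoff K, crossings of O_control = K mark values beyond
    which (towards the adjacent tail) a new measurement favors the control
    group at that grade; crossings of O_control = 1/K favor the ASD group.
    A metal can yield zero thresholds (curve never reaching a cutoff), one,
    or both a lower and an upper threshold (non-monotone odds).
    """
    levels = levels or ODDS_LEVELS
    rows: list[ThresholdRow] = []
    y = curve.log_odds_control
    for level, K in levels.items():
        for favored, c in (("control", np.log(K)), ("ASD", -np.log(K))):
            exceeds = y >= c if favored == "control" else y <= c
            for x0 in _crossings(curve.grid, y, c):
                # which side of the crossing satisfies the cutoff?
                i = int(np.searchsorted(curve.grid, x0))
                left = exceeds[max(i - 1, 0)]
                side = "below" if left else "above"
                rows.append(ThresholdRow(metal=curve.metal, level=level,
                                         threshold=x0, side=side, favored=favored))
    rows.sort(key=lambda r: (r.metal, r.level, r.threshold))
    return ThresholdTable(rows=rows, unit=unit)


def threshold_table(draws_control: PosteriorDraws, draws_asd: PosteriorDraws,
                    metals=None, unit: str = "", **grid_kw) -> ThresholdTable:
    """Thresholds for every metal of a pair of group fits, one odds curve each."""
    metals = metals or draws_control.metals
    rows: list[ThresholdRow] = []
    for metal in metals:
        curve = odds_curve(metal, draws_control, draws_asd, **grid_kw)
        rows.extend(find_thresholds(curve, unit=unit).rows)
    return ThresholdTable(rows=rows, unit=unit)
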