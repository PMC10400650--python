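"""Synthetic censored multivariate log-normal panels with known parameters.

The generator emulates the structure of a two-group biomonitoring study:
each individual's log-concentration vector is multivariate normal with
group-specific mean and covariance, every component falling below its
metal's detection limit is reported only as ``< limit``, and a small
fraction of cells is lost completely at random and recorded as an
interval-censored missing value.  Because the generating (mu, Sigma) are
known, every downstream stage (sampler, evidence grading, classification,
thresholds) can be tested without any study data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .panel import CellStatus, MetalPanel, canonical_stage

__all__ = ["GroupScenario", "generate_panel", "study_scale_scenario", "STUDY_METALS"]

#: analytes measured in the study design this package targets
STUDY_METALS = ["Al", "Cd", "Hg", "Li", "Pb", "Zn"]


@dataclass
class GroupScenario:
    """Generating parameters for one group.

    ``mu`` and ``sigma`` are on the log-concentration scale; detection
    limits and the implied concentrations are on the natural scale.
    """

    mu: np.ndarray  # (J,) log-scale means
    sigma: np.ndarray  # (J, J) log-scale covariance, symmetric PD
    n: int
    detection_limits: np.ndarray | None = None  # (J,) concentrations, or None
    missing_rate: float = 0.0
    metals: list[str] | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        J = self.mu.shape[0]
        if self.sigma.shape != (J, J):
            raise ValueError("sigma shape does not match mu")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        try:
            np.linalg.cholesky(self.sigma)
        except np.linalg.LinAlgError:
            raise ValueError("sigma must be positive definite") from None
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.detection_limits is not None:
            self.detection_limits = np.asarray(self.detection_limits, dtype=float)
            if self.detection_limits.shape != (J,):
                raise ValueError("detection_limits shape does not match mu")
            if not np.all(self.detection_limits > 0):
                raise ValueError("detection limits must be positive")

    @property
    def J(self) -> int:
        return self.mu.shape[0]

    def expected_censoring(self) -> np.ndarray:
        """Analytic per-metal probability of falling below the detection limit."""
        if self.detection_limits is None:
            return np.zeros(self.J)
        sd = np.sqrt(np.diag(self.sigma))
        return norm.cdf((np.log(self.detection_limits) - self.mu) / sd)


def _draw_group(scn: GroupScenario, rng: np.random.Generator) -> np.ndarray:
    L = np.linalg.cholesky(scn.sigma)
    z = rng.standard_normal((scn.n, scn.J))
    return np.exp(scn.mu + z @ L.T)


def generate_panel(scenario_asd: GroupScenario, scenario_control: GroupScenario,
                   stage: str, seed: int, unit: str = "ug/L") -> MetalPanel:
    """Draw one two-group panel; reproducible given ``seed``.

    Latent concentrations are exp of multivariate normal draws; components
    below the metal's detection limit become ``below_limit`` cells carrying
    that limit, and each cell is independently replaced by a missing-value
    interval with probability ``missing_rate`` (missing completely at
    random).  The default missing interval is [0, 10 x largest observed
    value of the metal in the panel], matching the loader's default for
    empty cells.
    """
    if scenario_asd.J != scenario_control.J:
        raise ValueError("scenarios must share the number of metals")
    metals = scenario_asd.metals or scenario_control.metals
    if metals is None:
        metals = [f"M{j + 1}" for j in range(scenario_asd.J)]
    if scenario_control.metals and scenario_asd.metals and scenario_control.metals != scenario_asd.metals:
        raise ValueError("scenarios must share the metal order")
    stage = canonical_stage(stage)
    rng = np.random.default_rng(seed)

    blocks, groups, ids = [], [], []
    for label, scn, prefix in (("ASD", scenario_asd, "A"), ("control", scenario_control, "C")):
        x = _draw_group(scn, rng)
        blocks.append((scn, x))
        groups += [label] * scn.n
        ids += [f"{stage}-{prefix}{i + 1:03d}" for i in range(scn.n)]

    n = len(ids)
    J = scenario_asd.J
    status = np.zeros((n, J), dtype=np.int8)
    value = np.full((n, J), np.nan)
    limit = np.full((n, J), np.nan)
    lo_arr = np.full((n, J), np.nan)
    hi_arr = np.full((n, J), np.nan)

    row = 0
    for scn, x in blocks:
        sl = slice(row, row + scn.n)
        value[sl] = x
        if scn.detection_limits is not None:
            cens = x < scn.detection_limits
            status[sl][cens] = CellStatus.BELOW_LIMIT
            limval = np.broadcast_to(scn.detection_limits, x.shape)
            lim_block = limit[sl]
            lim_block[cens] = limval[cens]
            limit[sl] = lim_block
            val_block = value[sl]
            val_block[cens] = np.nan
            value[sl] = val_block
        if scn.missing_rate > 0:
            miss = rng.random(x.shape) < scn.missing_rate
            st_block = status[sl]
            st_block[miss] = CellStatus.INTERVAL
            status[sl] = st_block
            for arr in (value, limit):
                blk = arr[sl]
                blk[miss] = np.nan
                arr[sl] = blk
        row += scn.n

    # default missing intervals from the realized panel
    for j in range(J):
        iv = status[:, j] == CellStatus.INTERVAL
        if not iv.any():
            continue
        obs = status[:, j] == CellStatus.OBSERVED
        if obs.any():
            ref = np.nanmax(value[obs, j])
        elif np.isfinite(limit[:, j]).any():
            ref = np.nanmax(limit[:, j])
        else:
            ref = 1.0
        lo_arr[iv, j] = 0.0
        hi_arr[iv, j] = 10.0 * ref

    return MetalPanel(
        metals=list(metals),
        ids=ids,
        group=np.array(groups, dtype=object),
        stage=np.array([stage] * n, dtype=object),
        status=status, value=value, limit=limit, lower=lo_arr, upper=hi_arr,
        unit=unit,
        meta={"seed": int(seed), "synthetic": True, "stage": stage},
    )


def _correlation(J: int, pairs: dict[tuple[int, int], float], base: float = 0.10) -> np.ndarray:
    R = np.full((J, J), base)
    np.fill_diagonal(R, 1.0)
    for (j, k), r in pairs.items():
        R[j, k] = R[k, j] = r
    np.linalg.cholesky(R)  # fail fast if not PD
    return R


def _cov(sd: np.ndarray, R: np.ndarray) -> np.ndarray:
    return R * np.outer(sd, sd)


def study_scale_scenario(kind: str, missing_rate: float = 0.02
                         ) -> tuple[GroupScenario, GroupScenario]:
    """Default two-group scenarios at the sizes of the target study design.

    ``kind='cord'`` gives n=20 (ASD) / n=40 (control); ``kind='five_year'``
    gives n=11 / n=24; both use the six metals Al, Cd, Hg, Li, Pb, Zn.

    The default parameters are order-of-magnitude plausible serum/cord
    concentrations in ug/L, not a reconstruction of any study's estimates.
    Group contrasts are qualitative: the ASD group runs higher in Al and Hg
    (with wider Al and Li spread), the control group has wider Zn and Pb
    spread, and the control correlation structure is stronger for the
    Pb-Al pair (|rho| >= 0.6).  Detection limits sit at the 44% point of
    each metal's pooled log-normal (average of the two groups' log-scale
    parameters), which places the analytic censoring fraction in the
    30-60% band for every metal in both groups.
    """
    kind = canonical_stage(kind)
    J = len(STUDY_METALS)
    # control log-scale location/spread per metal (Al, Cd, Hg, Li, Pb, Zn)
    mu_c = np.log(np.array([12.0, 0.06, 0.60, 1.00, 1.10, 900.0]))
    sd_c = np.array([0.65, 0.55, 0.70, 0.60, 0.55, 0.60])
    if kind == "five_year":
        mu_c = mu_c + np.array([1.00, 0.30, 0.15, 1.20, 0.50, -0.40])
    shift_a = (np.array([0.30, 0.00, 0.20, 0.10, -0.15, 0.00]) if kind == "cord"
               else np.array([0.00, 0.00, 0.50, 0.10, -0.10, 0.10]))
    sdmul_a = np.array([1.25, 1.00, 1.10, 1.30, 0.80, 0.75])
    mu_a = mu_c + shift_a
    sd_a = sd_c * sdmul_a

    idx = {m: j for j, m in enumerate(STUDY_METALS)}
    R_control = _correlation(J, {(idx["Pb"], idx["Al"]): 0.65,
                                 (idx["Al"], idx["Hg"]): 0.40,
                                 (idx["Pb"], idx["Li"]): 0.40,
                                 (idx["Zn"], idx["Cd"]): 0.35})
    R_asd = _correlation(J, {(idx["Pb"], idx["Al"]): 0.20,
                             (idx["Pb"], idx["Hg"]): 0.45,
                             (idx["Al"], idx["Hg"]): 0.15})

    limits = np.exp(0.5 * (mu_a + mu_c) + norm.ppf(0.44) * 0.5 * (sd_a + sd_c))
    n_asd, n_ctrl = (20, 40) if kind == "cord" else (11, 24)
    asd = GroupScenario(mu=mu_a, sigma=_cov(sd_a, R_asd), n=n_asd,
                        detection_limits=limits, missing_rate=missing_rate,
                        metals=list(STUDY_METALS))
    ctrl = GroupScenario(mu=mu_c, sigma=_cov(sd_c, R_control), n=n_ctrl,
                         detection_limits=limits, missing_rate=missing_rate,
                         metals=list(STUDY_METALS))
    return asd, ctrl
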