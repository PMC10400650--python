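import warnings

import numpy as np
import pytest
from hypothesis import settings

from bayeslod.panel import MetalPanel, CellStatus
from bayeslod.simulate import GroupScenario, generate_panel, study_scale_scenario

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

warnings.filterwarnings("ignore", message=".*ArviZ is undergoing.*")


def make_panel(status, value=None, limit=None, lower=None, upper=None,
               metals=None, groups=None, stages=None, unit="ug/L"):
    """Hand-rolled panel from dense arrays; NaN-filled fields default."""
    status = np.asarray(status, dtype=np.int8)
    n, J = status.shape

    def arr(a):
        return np.full((n, J), np.nan) if a is None else np.asarray(a, dtype=float)

    return MetalPanel(
        metals=metals or [f"M{j + 1}" for j in range(J)],
        ids=[f"i{i}" for i in range(n)],
        group=np.array(groups or ["ASD"] * (n // 2) + ["control"] * (n - n // 2), dtype=object),
        stage=np.array(stages or ["cord"] * n, dtype=object),
        status=status, value=arr(value), limit=arr(limit),
        lower=arr(lower), upper=arr(upper), unit=unit)


@pytest.fixture
def toy_panel():
    """4 individuals x 2 metals; one Hg cell below limit, one interval."""
    O, B, I = CellStatus.OBSERVED, CellStatus.BELOW_LIMIT, CellStatus.INTERVAL
    return make_panel(
        status=[[O, B], [O, O], [O, O], [I, O]],
        value=[[5.0, np.nan], [2.0, 0.8], [3.0, 0.4], [np.nan, 0.6]],
        limit=[[np.nan, 0.5]] + [[np.nan, np.nan]] * 3,
        lower=[[np.nan] * 2] * 3 + [[0.0, np.nan]],
        upper=[[np.nan] * 2] * 3 + [[50.0, np.nan]],
        metals=["Al", "Hg"],
        groups=["ASD", "ASD", "control", "control"])


@pytest.fixture(scope="session")
def cord_panel():
    asd, ctrl = study_scale_scenario("cord")
    return generate_panel(asd, ctrl, "cord", seed=20240)


@pytest.fixture(scope="session")
def small_fit():
    """A cheap censored fit (J=2, n=60) shared by downstream-module tests."""
    from bayeslod.gibbs import gibbs_fit
    rng_mu = np.array([0.0, 1.0])
    sig = np.array([[0.8, 0.3], [0.3, 0.6]])
    scn_a = GroupScenario(mu=rng_mu + 0.4, sigma=sig, n=30,
                          detection_limits=np.exp(rng_mu - 0.1), metals=["A", "B"])
    scn_c = GroupScenario(mu=rng_mu, sigma=sig, n=30,
                          detection_limits=np.exp(rng_mu - 0.1), metals=["A", "B"])
    panel = generate_panel(scn_a, scn_c, "cord", seed=77)
    d_a, _ = gibbs_fit(panel.subset(group="ASD"), n_chains=2, n_iter=1500, n_burnin=500, seed=1)
    d_c, _ = gibbs_fit(panel.subset(group="control"), n_chains=2, n_iter=1500, n_burnin=500, seed=2)
    return d_a, d_c
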