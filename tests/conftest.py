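import numpy as np
import pandas as pd
import pytest

from msplinesim import dgm as dgm_mod
from msplinesim.hazard_model import ModelSpec
from msplinesim.spline_basis import place_knots


@pytest.fixture(scope="session")
def fixtures():
    return dgm_mod.fixture_dgms()


@pytest.fixture(scope="session")
def os_dgm(fixtures):
    return fixtures["os_like"]


@pytest.fixture(scope="session")
def exp_data():
    """Right-censored exponential sample (lambda = 0.5, censoring at 5y)."""
    rng = np.random.default_rng(42)
    t = rng.exponential(2.0, 400)
    return pd.DataFrame(
        {"time": np.minimum(t, 5.0), "event": (t <= 5.0).astype(int)}
    )


@pytest.fixture(scope="session")
def os_trial(os_dgm):
    """One simulated single-arm trial from the os_like truth model."""
    return dgm_mod.simulate_trial(os_dgm, None, 200, 5.0, seed=7).data


@pytest.fixture(scope="session")
def os_spec(os_trial):
    uncensored = os_trial.loc[os_trial["event"] == 1, "time"].to_numpy()
    basis = place_knots(uncensored, df=10, lower=0.0,
                        upper=float(os_trial["time"].max()))
    return ModelSpec(basis=basis)


@pytest.fixture(scope="session")
def weibull_dgm():
    """Royston-Parmar truth with no internal knots: Weibull H = exp(g0) t^g1."""
    return dgm_mod.RoystonParmarDGM(
        knots=np.log([0.05, 8.0]), gamma=np.array([-0.5, 1.3]), label="weibull"
    )
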