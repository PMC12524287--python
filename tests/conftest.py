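import numpy as np
import pandas as pd
import pytest

from occumap import ModelSpec, RoyleNichols, simulate_stations
from occumap.simulate import SimulationConfig


def rn_dataset(seed, n=300, J=8, beta0=0.0, beta_x=None, r=0.3, sites=1,
               site_effects=None, deployment_days=None):
    """One simulated survey with fixed J occasions (single missingness cohort
    unless deployment_days is a range). Returns (history, covariates, truth)."""
    beta = {"(Intercept)": beta0}
    cov_spec = []
    if beta_x is not None:
        beta["x"] = beta_x
        cov_spec.append(("x", "normal", (0.0, 1.0)))
    cfg = SimulationConfig(
        n_sites=sites,
        stations_per_site=int(np.ceil(n / sites)),
        deployment_days=deployment_days or (J * 5, J * 5),
        window_days=5,
        beta=beta,
        covariate_spec=tuple(cov_spec),
        site_effects=site_effects if site_effects is not None else [0.0] * sites,
        alpha_intercept=float(np.log(r / (1 - r))),
        seed=seed,
    )
    dep, cov, truth = simulate_stations(cfg)
    return truth.history, cov, truth


@pytest.fixture(scope="session")
def small_fit():
    """A converged intercept-only Royle-Nichols fit on a small survey."""
    history, cov, _ = rn_dataset(seed=42, n=80, J=6)
    return RoyleNichols(history, cov, ModelSpec()).fit(restarts=1, seed=0)


@pytest.fixture
def toy_records():
    return pd.DataFrame(
        {
            "station_id": ["A", "A", "A"],
            "timestamp": ["2021-01-05T10:00", "2021-01-05T10:15", "2021-01-05T10:45"],
        }
    )
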