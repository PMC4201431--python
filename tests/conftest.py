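import numpy as np
import pandas as pd
import pytest

from nmixtures import CountDataset, SimScenario, simulate_study, study_scenario


@pytest.fixture
def tiny_dataset():
    """Four sites, two seasons, two visits, deterministic covariates."""
    rng = np.random.default_rng(42)
    n_sites = 4
    sites = pd.DataFrame(
        {
            "site": [f"s{i}" for i in range(n_sites)],
            "snag_ba": [1.0, 3.0, 5.0, 2.0],
            "conifer_ba": [0.5, 1.5, 0.0, 2.0],
            "boxes": [0, 1, 0, 1],
        }
    )
    rows = []
    for i in range(n_sites):
        for t in (1, 2):
            for j in (1, 2):
                rows.append(
                    {
                        "site": f"s{i}",
                        "season": t,
                        "visit": j,
                        "count": int(rng.integers(0, 4)),
                        "precip": float(rng.gamma(2.0, 3.0)),
                        "julian_day": float(rng.integers(250, 335)),
                        "height": (i + j) % 2,
                        "year": t - 1,
                    }
                )
    return CountDataset(pd.DataFrame(rows), sites)


@pytest.fixture(scope="session")
def study_sim():
    """One synthetic draw of the default study scenario (56 sites)."""
    return simulate_study(study_scenario(), seed=11)


@pytest.fixture(scope="session")
def intercept_scenario():
    """Intercept-only generating truth for recovery-style checks."""
    return SimScenario(
        n_sites=200,
        n_treated=100,
        lambda_coefs={"(Intercept)": float(np.log(2.0))},
        psi=0.0,
        gamma_coefs={"(Intercept)": float(np.log(3.0))},
        omega=0.6,
        p_coefs={"(Intercept)": float(np.log(0.4 / 0.6))},
    )
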