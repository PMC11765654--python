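import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table2_counts():
    from canopymed.stratification import load_table2_counts

    return load_table2_counts()


@pytest.fixture(scope="session")
def small_study():
    """One complete-data synthetic study at moderate scale, shared across tests."""
    from canopymed import synthetic

    cfg = synthetic.GeneratorConfig()
    ds = synthetic.gen_dataset(cfg, seed=404, n_captures=800, oracle_K=400_000)
    cap = ds["captures"].copy()
    cap["LD"] = ds["truth"].capture_LD
    cap["TD"] = ds["truth"].capture_TD
    ds["captures_complete"] = cap
    return ds


@pytest.fixture(scope="session")
def fitted_posterior(small_study):
    """A converged-ish posterior on the shared study, reused by several tests."""
    from canopymed import mediation

    model = mediation.build_joint_model(
        small_study["captures_complete"], small_study["fct_priors"]
    )
    return mediation.fit(
        model, chains=2, warmup=400, draws=600, seed=77, thin=3
    )
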