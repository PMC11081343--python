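"""Shared fixtures: the study simulation and a fitted joint model.

The expensive session fixtures (the n=20,000 simulated cohort and its ADVI
fit) are created once and shared by the recovery, discrimination and
interpretation tests.
"""

import numpy as np
import pytest

import quiltsurv as q
from quiltsurv.advi import QuiltProblem, TrainConfig, fit
from quiltsurv.model import ModelData, QuiltModel, QuiltModelConfig
from quiltsurv.pem import PEMConfig

FIXTURE_SEED = 20240509


@pytest.fixture(scope="session")
def fixture_sim():
    """The default synthetic study cohort (n=20,000, p=10, 2×2 lattice)."""
    cfg = q.fixture_config(seed=FIXTURE_SEED)
    df, truth = q.simulate(cfg)
    return cfg, df, truth


@pytest.fixture(scope="session")
def fixture_data(fixture_sim):
    cfg, df, truth = fixture_sim
    pem = PEMConfig()
    time = np.maximum(df["time"].to_numpy(), pem.min_wait_days)
    return ModelData.build(truth.design, truth.kappas,
                           df["placement"].to_numpy(), time,
                           df["event"].to_numpy(), cfg.lattice, pem)


@pytest.fixture(scope="session")
def fitted_fixture(fixture_sim, fixture_data):
    """ADVI fit of the joint model on the study cohort (desk-scale batches)."""
    cfg, df, truth = fixture_sim
    model = QuiltModel(QuiltModelConfig(cfg.lattice, truth.design.shape[1],
                                        PEMConfig()))
    model.column_names = truth.column_names
    posterior = fit(QuiltProblem(model, fixture_data),
                    TrainConfig(batch_size=1000, seed=1))
    return model, posterior


@pytest.fixture(scope="session")
def small_sim():
    """A fast small cohort for schema / smoke tests."""
    cfg = q.fixture_config(seed=7, n=1500)
    df, truth = q.simulate(cfg)
    return cfg, df, truth
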