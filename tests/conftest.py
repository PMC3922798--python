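import numpy as np
import pytest

import pmcalib as pm


@pytest.fixture(scope="session")
def small_dataset():
    """A modest regression-truth panel shared across read-only tests."""
    cfg = pm.SimulationConfig(
        n_cities=5, subjects_per_city=10, months_per_subject=6, seed=42
    )
    return pm.simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return pm.build_analysis_table(
        small_dataset.daily, small_dataset.monitors, small_dataset.model_pred
    )


def simulate_table(**kwargs):
    """Simulate a panel and build its analysis table in one step."""
    cfg = pm.SimulationConfig(**kwargs)
    ds = pm.simulate_panel(cfg)
    table = pm.build_analysis_table(ds.daily, ds.monitors, ds.model_pred)
    return ds, table


@pytest.fixture(scope="session")
def toy_balanced():
    """Hand-sized balanced layout (2 cities x 2 subjects x 4 months, 16 obs)
    for closed-form oracle checks."""
    rng = np.random.default_rng(5)
    city = np.repeat([0, 1], 8)
    subj = np.repeat([0, 1, 2, 3], 4)
    z = rng.normal(15, 4, 16)
    y = 2 + 0.5 * z + rng.normal(0, 1, 16)
    X = np.column_stack([np.ones(16), z])
    return {"city": city, "subj": subj, "z": z, "y": y, "X": X}
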