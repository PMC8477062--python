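import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dendrocomp as dc

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def plot_sim() -> dc.GrowthSimulation:
    """One simulated 600 trees/ha plot under the default study conditions."""
    return dc.simulate_plot(dc.SimulationConfig(seed=2))


@pytest.fixture(scope="session")
def site_sim() -> dc.SiteSimulation:
    """One simulated site: shared climate, three density classes."""
    return dc.simulate_site(dc.SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def stationary_climate() -> dc.ClimateSeries:
    """A 200-year drought-free climate for distributional checks."""
    cfg = dc.SimulationConfig(seed=9, n_years=200, drought_years=())
    return dc.gen_climate(cfg)


@pytest.fixture()
def tiny_stand() -> dc.StandInventory:
    """Hand-built 3-tree stand with easy geometry."""
    trees = pd.DataFrame({
        "tree_id": ["a", "b", "c"],
        "x_m": [10.0, 11.0, 10.0],
        "y_m": [10.0, 10.0, 12.0],
        "dbh_cm": [20.0, 20.0, 40.0],
        "height_m": [12.0, 12.0, 15.0],
        "cored": [True, False, False],
    })
    return dc.StandInventory(plot_id="T", width_m=30.0, height_m=30.0,
                             planting_year=1980, trees=trees)


def brute_force_hegyi(stand: dc.StandInventory, radius: float = 8.0) -> dict:
    """Independent O(n²) loop oracle for the Hegyi index."""
    t = stand.trees
    out = {}
    for i in range(len(t)):
        ci = 0.0
        for j in range(len(t)):
            if i == j:
                continue
            d = np.hypot(t.x_m[i] - t.x_m[j], t.y_m[i] - t.y_m[j])
            if d <= radius:
                ci += (t.dbh_cm[j] / t.dbh_cm[i]) / d
        out[t.tree_id[i]] = ci
    return out
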