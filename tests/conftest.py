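import numpy as np
import pandas as pd
import pytest

from dustshed.model import CovarianceParams
from dustshed.simulate import SimulationTruth, make_layout, simulate_richness


@pytest.fixture(scope="session")
def default_truth():
    return SimulationTruth(seed=11)


@pytest.fixture(scope="session")
def layout(default_truth):
    return make_layout(seed=default_truth.seed)


@pytest.fixture(scope="session")
def plots(layout, default_truth):
    return simulate_richness(layout, default_truth)


@pytest.fixture()
def small_plot_table():
    """A tiny hand-written plot table."""
    return pd.DataFrame(
        {
            "plot_id": ["A", "B", "C"],
            "x": [0.0, 100.0, 200.0],
            "y": [10.0, -50.0, 100.0],
            "dist_road": [10.0, 50.0, 100.0],
            "side": ["north", "south", "north"],
            "habitat": ["ericaceous_shrub", "tussock_tundra", "ericaceous_shrub"],
            "richness": [3, 7, 12],
        }
    )


@pytest.fixture()
def nonspatial_truth():
    """Pure Poisson regression truth: no spatial noise."""
    return SimulationTruth(theta=CovarianceParams(1e-9, 0.0, 800.0), seed=3)
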