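import pandas as pd
import pytest

from airwaysim import config as cfgmod
from airwaysim import flow_network as fn
from airwaysim import synthetic_data as sd


@pytest.fixture(scope="session")
def cfg():
    return cfgmod.default_config()


@pytest.fixture(scope="session")
def correlations(cfg):
    return cfgmod.correlations(cfg)


@pytest.fixture(scope="session")
def characteristic_tree():
    """The packaged, calibrated characteristic airway model."""
    return sd.default_tree()


@pytest.fixture(scope="session")
def cycle():
    return fn.BreathingCycle()


@pytest.fixture(scope="session")
def transient_series(characteristic_tree, cycle):
    return fn.solve_transient(characteristic_tree, cycle, dt=0.01)


@pytest.fixture(scope="session")
def weibel_tree():
    from airwaysim import morphometry as mm

    recipe = sd.TreeRecipe(mode="weibel_symmetric")
    return mm.build_tree(sd.make_weibel_table(recipe))


@pytest.fixture()
def single_tube_table():
    return pd.DataFrame(
        [
            {
                "id": "b",
                "parent_id": "",
                "generation": 0,
                "length_cm": 10.0,
                "diameter_cm": 1.56,
                "dx": 0.0,
                "dy": 0.0,
                "dz": -1.0,
                "lobe": "RLL",
                "region": "trachea",
            }
        ]
    )


def two_outlet_table(d_a=0.8, d_b=0.8, l_a=3.0, l_b=3.0):
    rows = [
        {"id": "b", "parent_id": "", "generation": 0, "length_cm": 10.0, "diameter_cm": 1.56, "dx": 0, "dy": 0, "dz": -1, "lobe": "none", "region": "trachea"},
        {"id": "b0", "parent_id": "b", "generation": 1, "length_cm": l_a, "diameter_cm": d_a, "dx": 0.5, "dy": 0, "dz": -0.866, "lobe": "RLL", "region": "bif1"},
        {"id": "b1", "parent_id": "b", "generation": 1, "length_cm": l_b, "diameter_cm": d_b, "dx": -0.5, "dy": 0, "dz": -0.866, "lobe": "LLL", "region": "bif1"},
    ]
    return pd.DataFrame(rows)
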