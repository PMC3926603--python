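import numpy as np
import pytest

from insolekit.sensor_model import AGGREGATE_MODEL, default_layout
from insolekit.synthetic import GaitScenario, generate_trial
from insolekit.workflow import process_trial


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def model():
    return AGGREGATE_MODEL


@pytest.fixture(scope="session")
def short_trial():
    """A 7-step simulated trial (3 steady-state steps after trimming)."""
    scenario = GaitScenario(n_steps=7, seed=1)
    left, right, truth = generate_trial(scenario)
    return scenario, left, right, truth


@pytest.fixture(scope="session")
def short_result(short_trial):
    _, left, right, _ = short_trial
    return process_trial(left, right)


def make_biomech_frame(vgrf, cop_y, fs_hz=100.0):
    """Build a biomech DataFrame from vgrf / cop_y arrays (NaN cop = swing)."""
    import pandas as pd

    vgrf = np.asarray(vgrf, dtype=float)
    cop_y = np.asarray(cop_y, dtype=float)
    return pd.DataFrame(
        {
            "time_s": np.arange(len(vgrf)) / fs_hz,
            "vgrf_N": vgrf,
            "cop_x_mm": np.where(np.isnan(cop_y), np.nan, 45.0),
            "cop_y_mm": cop_y,
        }
    )
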