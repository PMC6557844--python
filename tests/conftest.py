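import numpy as np
import pandas as pd
import pytest

from endoepi import EnergeticsParams, shipped_archetypes


@pytest.fixture(scope="session")
def params() -> EnergeticsParams:
    return EnergeticsParams()


@pytest.fixture(scope="session")
def mda_archetype():
    return next(a for a in shipped_archetypes() if a.name == "MDA-MB-231")


@pytest.fixture
def circle_table() -> pd.DataFrame:
    """A condition in which every cell is a perfect circle."""
    n = 10
    return pd.DataFrame(
        {
            "condition": "circles",
            "cell_id": [f"c{i}" for i in range(n)],
            "on_vessel": [i % 2 == 0 for i in range(n)],
            "major_axis_um": np.full(n, 10.0),
            "minor_axis_um": np.full(n, 10.0),
            "fluorescence": np.full(n, 1.0),
        }
    )
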