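import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bafkit.io_formats import Plate, PlateMap

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_luv_plate() -> Plate:
    """Three-timepoint plate with one buffer, one CHAPS, one sample well."""
    pm = PlateMap(
        pd.DataFrame(
            {
                "well": ["A01", "A02", "A03"],
                "condition": ["buffer", "chaps", "bax"],
                "role": ["buffer", "detergent_max", "sample"],
                "dose_a": [0.0, 0.0, 1.0],
                "dose_b": [0.0, 0.0, 0.0],
                "replicate": [1, 1, 1],
            }
        )
    )
    signals = pd.DataFrame(
        {
            "A01": [10.0, 12.0, 9.0],
            "A02": [200.0, 220.0, 210.0],
            "A03": [50.0, 120.0, 180.0],
        },
        index=pd.Index([55.0, 110.0, 165.0], name="time_s"),
    )
    return Plate(signals=signals, plate_map=pm)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
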