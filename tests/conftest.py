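import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from synkit import GroupConfig, build_group


@pytest.fixture
def tiny_frame() -> pd.DataFrame:
    """Two participants, symbols A and B, three trials each."""
    rows = []
    colors = {
        ("p1", "A"): ["#FF0000", "#FE0100", "#FF0202"],
        ("p1", "B"): ["#00FF00", "#01FE00", "#02FF02"],
        ("p2", "A"): ["#0000FF", "#FFFFFF", ""],
        ("p2", "B"): ["#000000", "#000000", "#000000"],
    }
    for (pid, sym), hexes in colors.items():
        for h in hexes:
            rows.append({"participant_id": pid, "symbol": sym, "color": h})
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_group(tiny_frame):
    return build_group(tiny_frame, GroupConfig(color_space="sRGB"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231101)
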