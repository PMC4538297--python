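import numpy as np
import pandas as pd
import pytest

from britepipe import ExpressionMatrix, PlantedSignal, SimConfig


@pytest.fixture
def two_group_meta():
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "group": ["A"] * 3 + ["B"] * 3,
            "timepoint": ["8d"] * 6,
            "ne_status": ["-NE"] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )


@pytest.fixture
def small_log2_matrix(two_group_meta):
    rng = np.random.default_rng(42)
    X = rng.normal(8.0, 1.0, (60, 6))
    df = pd.DataFrame(
        X, index=[f"G{i:03d}" for i in range(60)], columns=two_group_meta["sample_id"]
    )
    return ExpressionMatrix(df, scale="log2")


@pytest.fixture
def tiny_two_group_config():
    """3 vs 3 bead experiment with one planted up-shifted block."""
    return SimConfig(
        n_probes=200,
        n_sets=5,
        set_size_range=(10, 40),
        groups=("Control", "cPGI2"),
        timepoints=("8d",),
        noise_sd=0.25,
        effect_size=1.0,
        signals=(PlantedSignal("up", 20, ("cPGI2",), ("8d",), +1),),
        seed=7,
    )
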