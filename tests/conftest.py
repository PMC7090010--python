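import numpy as np
import pandas as pd
import pytest

from inteinscreen.assembly_planner import InteinSpec
from inteinscreen.orthogonality import CrossMatrix, SplitPair
from inteinscreen.synthetic_data import GeneratorConfig


@pytest.fixture
def small_plate():
    """One plate, two wells (blank + test), mCherry and OD600 at t=0."""
    readings = pd.DataFrame(
        {
            "plate_id": ["P1"] * 4,
            "well": ["A1", "A1", "A2", "A2"],
            "sample_id": ["blank", "blank", "s1", "s1"],
            "channel": ["mCherry", "OD600", "mCherry", "OD600"],
            "time_s": [0.0] * 4,
            "value": [100.0, 0.04, 5000.0, 0.529],
        }
    )
    layout = pd.DataFrame(
        {
            "sample_id": ["blank", "s1", "ctrl"],
            "role": ["blank_medium", "test", "negative_control"],
            "replicate_group": ["blank", "g1", "ctrl"],
        }
    )
    return readings, layout


def make_matrix(rel: np.ndarray, cognate: float = 1000.0) -> CrossMatrix:
    """CrossMatrix from a relative-level grid (diagonal forced to 1)."""
    rel = np.asarray(rel, dtype=float).copy()
    np.fill_diagonal(rel, 1.0)
    k = rel.shape[0]
    pairs = [SplitPair(f"I{i + 1:02d}", "S2") for i in range(k)]
    return CrossMatrix(pairs, cognate * rel)


@pytest.fixture
def clean_matrix_4():
    """4x4 matrix with zero cross-talk."""
    return make_matrix(np.zeros((4, 4)))


@pytest.fixture
def intein_library():
    return [
        InteinSpec("gp41-1", "YCMSGE"),
        InteinSpec("gp41-8", "YSTSGE"),
        InteinSpec("NrdJ-1", "YCGSSE"),
        InteinSpec("IMPDH-1", "YCGSAE"),
        InteinSpec("SspGyrB", "YCLSYE"),
    ]


@pytest.fixture
def base_config():
    return GeneratorConfig(seed=42)
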