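import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from spnnet import WeightedGraph, desk_spec, generate_cohort


def make_graph(w: np.ndarray) -> WeightedGraph:
    return WeightedGraph(
        node_ids=[f"n{i}" for i in range(w.shape[0])], weights=np.asarray(w, float)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def desk_cohort():
    """Small planted cohort shared by the slower end-to-end tests."""
    spec = desk_spec(seed=11, group_attenuation=0.3, noise_sd=0.5)
    return spec, generate_cohort(spec)
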