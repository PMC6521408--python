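import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from decoytools import FixtureConfig, synth
from decoytools.components import DesignTable


@pytest.fixture
def small_table() -> DesignTable:
    """Three 4-residue decoys used across selection/mutation tests."""
    t = DesignTable({
        "score": [-12.0, -10.0, -8.0],
        "description": ["d1", "d2", "d3"],
        "sequence_A": ["AAAA", "CAAA", "CACA"],
    })
    return t


@pytest.fixture
def small_cfg() -> FixtureConfig:
    """Scaled-down corpus: quick to generate, same structure as defaults."""
    return FixtureConfig(seed=7, n_decoys=200, n_neighbors=10)


@pytest.fixture
def study_cfg() -> FixtureConfig:
    """The default study conditions (n=1000, margin 0.30, 4 positions)."""
    return FixtureConfig(seed=0)


@pytest.fixture
def helix_structure(small_cfg):
    return synth.make_backbone(small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
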