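import numpy as np
import pytest

from wsimil.omics import PathwayDefinition
from wsimil.preprocess import Tile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pathway_defs():
    return [
        PathwayDefinition("p53", [("TP53", -1), ("MDM2", 1)]),
        PathwayDefinition("cell_cycle", [("RB1", -1), ("CCND1", 1), ("CDK4", 1)]),
        PathwayDefinition("myc", [("MYC", 1)]),
    ]


def make_tile(value=128, size=16, pos=(0, 0), slide_id="s"):
    return Tile(np.full((size, size, 3), value, dtype=np.uint8), pos, slide_id)


@pytest.fixture
def constant_tile():
    return make_tile
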