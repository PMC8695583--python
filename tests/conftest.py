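from pathlib import Path

import pytest

from spacerscreen import screen_pipeline as sp
from spacerscreen import synthetic_library as sim

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_cfg() -> sim.SimConfig:
    return sim.SimConfig(seed=1)


@pytest.fixture(scope="session")
def picked_clones(default_cfg):
    """Post-selection 96-colonies-per-length library (the screen input)."""
    return sim.pick_colonies(default_cfg)


@pytest.fixture(scope="session")
def screen_norm(default_cfg, picked_clones):
    """Normalized mirrored treated/untreated endpoint screen."""
    raw = sim.simulate_screen_pair(picked_clones, default_cfg)
    return sp.normalize(raw)


@pytest.fixture(scope="session")
def promoter_fixture_path() -> Path:
    return DATA / "promoters_regulondb_like.synthetic.tsv"
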