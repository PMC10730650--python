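import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from melanoclime.pipeline import run_pipeline
from melanoclime.world import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world (the study condition, master seed 0)."""
    return generate_world(WorldConfig())


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default world with the standard 1000-draw null."""
    return run_pipeline(WorldConfig(), n_null_draws=1000)


@pytest.fixture(scope="session")
def small_config():
    """A fast, small world for smoke and determinism checks."""
    return WorldConfig(nx=20, ny=20, n_species=60, seed=7)
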