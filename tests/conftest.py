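from pathlib import Path

import pytest

from amplicall.calling import FilterConfig
from amplicall.sim import DilutionSpec, SimConfig, build_synthetic_panel

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_panel_path() -> Path:
    return DATA_DIR / "toy_panel.tsv"


@pytest.fixture(scope="session")
def panel_and_sites():
    """Small synthetic panel with 4 truth sites plus 4 background amplicons."""
    return build_synthetic_panel(n_amplicons=8, per_pool=8, n_sites=4, seed=7)


@pytest.fixture(scope="session")
def fast_sim_config() -> SimConfig:
    """Reduced-depth simulator settings for quick unit tests."""
    return SimConfig(target_depth=600)


@pytest.fixture
def cfg() -> FilterConfig:
    return FilterConfig()
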