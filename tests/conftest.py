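import numpy as np
import pandas as pd
import pytest

from edstack.curation import curate_frames
from edstack.synthetic import GeneratorConfig, generate, generate_panel, reference_fixture


@pytest.fixture(scope="session")
def default_panel():
    """Curated panel + ground truth at the default 76x24 configuration."""
    panel, log, truth, frames = generate_panel(GeneratorConfig(seed=0))
    return panel, log, truth, frames


@pytest.fixture(scope="session")
def small_panel():
    """A small panel (20 regions) for split/CV mechanics tests."""
    panel, log, truth, frames = generate_panel(GeneratorConfig(n_regions=20, seed=1))
    return panel, log, truth, frames


@pytest.fixture(scope="session")
def ref_fixture():
    """The study-shaped fixture: raw frames, curated panel and log."""
    frames, truth = reference_fixture(seed=0)
    panel, log = curate_frames(
        frames["providers"], frames["contracts"], frames["contract_map"],
        frames["gp"], frames["regions"],
    )
    return frames, truth, panel, log


@pytest.fixture()
def tiny_registry():
    from edstack.curation import RegionRegistry

    frame = pd.DataFrame(
        {
            "region_id": ["A", "A", "B", "B", "C", "C"],
            "year": [2018, 2019] * 3,
            "population": [100_000, 101_000, 300_000, 303_000, 50_000, 50_500],
            "population_over_65": [19_000, 19_500, 60_000, 61_000, 10_000, 10_100],
            "people": [96.0, 96.5, 104.0, 104.5, 100.0, 100.5],
            "places": [99.0, 99.0, 101.0, 101.0, 100.0, 100.0],
            "lives": [95.0, 95.5, 105.0, 105.0, 100.0, 100.0],
            "merger_group": ["", "", "", "", "", ""],
        }
    )
    return RegionRegistry(frame)


def rng(seed=0):
    return np.random.default_rng(seed)
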