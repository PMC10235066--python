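import logging

import pytest

from pacarbon import LandscapeConfig, RunConfig
from pacarbon.pipeline import run_pipeline
from pacarbon.synthetic import generate_landscape, sample_footprints

logging.getLogger("pacarbon").setLevel(logging.WARNING)


def small_config(seed: int = 3, **overrides) -> LandscapeConfig:
    """A fast 30x30 world with 6 small PAs for unit tests."""
    defaults = dict(grid_rows=30, grid_cols=30, n_countries=2, n_biomes=2,
                    n_ecoregions=2, n_landcovers=2, n_pas=6,
                    pa_halfwidth_range=(1, 1), seed=seed)
    defaults.update(overrides)
    return LandscapeConfig(**defaults)


def small_run_config(seed: int = 3, **overrides) -> RunConfig:
    overrides.setdefault("buffer_km", 3.0)
    return RunConfig(seed=seed, landscape=small_config(seed), **overrides)


@pytest.fixture(scope="session")
def small_world():
    landscape = generate_landscape(small_config())
    shots = sample_footprints(landscape)
    return landscape, shots


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size pipeline run shared by integration-style tests."""
    cfg = RunConfig(seed=3, landscape=LandscapeConfig(seed=3))
    return run_pipeline(cfg)
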