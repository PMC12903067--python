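import numpy as np
import pytest

from msibatchqc.datacube import Datacube
from msibatchqc.synthdata import SynthConfig, simulate_study


def make_cube(
    n_per_section: int = 9,
    sections=("s1", "s2"),
    batches=(1, 2),
    n_features: int = 5,
    seed: int = 0,
    tissue: str = "sample",
) -> Datacube:
    """Small random cube: one section per batch, 3x3 grids by default."""
    rng = np.random.default_rng(seed)
    side = int(np.sqrt(n_per_section))
    assert side * side == n_per_section
    n = n_per_section * len(sections)
    ys, xs = np.divmod(np.arange(n_per_section), side)
    return Datacube(
        intensities=rng.uniform(1, 10, size=(n, n_features)),
        mz=100.0 + np.arange(n_features),
        pixel_x=np.tile(xs, len(sections)),
        pixel_y=np.tile(ys, len(sections)),
        section_id=np.repeat(np.array(sections, dtype=object), n_per_section),
        slide_id=np.repeat(np.array(sections, dtype=object), n_per_section),
        batch=np.repeat(np.array(batches, dtype=int), n_per_section),
        time_s=np.arange(n, dtype=float),
        tissue=np.full(n, tissue, dtype=object),
    )


@pytest.fixture
def small_cube() -> Datacube:
    return make_cube()


@pytest.fixture(scope="session")
def default_study():
    """One draw of the default 10-batch study, shared across tests."""
    return simulate_study(SynthConfig(), seed=11)


@pytest.fixture(scope="session")
def correlated_study():
    """Correlated-ion study: one shared multiplicative batch factor per batch."""
    cfg = SynthConfig(
        n_batches=5,
        grid_width=12,
        grid_height=12,
        n_features=30,
        batch_loc_sd_ion=0.0,
        batch_loc_sd_shared=0.4,
    )
    return cfg, simulate_study(cfg, seed=2)
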