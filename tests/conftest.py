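import numpy as np
import pytest

from mapqc import fixtures
from mapqc.core_io import VoxelGrid


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture()
def random_grid(rng):
    """A 16³ grid of standard-normal voxels at 1 Å/voxel."""
    return VoxelGrid(rng.normal(size=(16, 16, 16)))


@pytest.fixture(scope="session")
def toy_model():
    return fixtures.make_toy_model(20, seed=7)


@pytest.fixture(scope="session")
def clean_signal():
    """Noiseless simulated density of the centered toy model on a 64³ lattice."""
    spec = fixtures.FixtureSpec(seed=7, noise_sigma=0.0)
    model = fixtures._centered_model(fixtures.make_toy_model(20, 7), spec)
    return fixtures.make_synthetic_map(model, spec), model


@pytest.fixture(scope="session")
def clean_entry(tmp_path_factory):
    """A written-out clean scenario entry directory."""
    out = tmp_path_factory.mktemp("entry_clean")
    spec = fixtures.FixtureSpec(seed=11)
    manifest = fixtures.make_scenario(spec, out)
    return out, manifest, spec
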