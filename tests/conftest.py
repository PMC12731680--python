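import numpy as np
import pytest

from crackspec.core import SpectralCube, WavelengthGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.linspace(1000.0, 2500.0, 12))


@pytest.fixture
def small_cube(rng, small_grid):
    data = rng.random((6, 7, 12), dtype=np.float32)
    return SpectralCube(data=data, grid=small_grid, kind="reflectance",
                        provenance="fixture")
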