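import numpy as np
import pytest

from mirrortract import phantom as ph
from mirrortract.config import RunConfig
from mirrortract.volumes import GridSpec, MaskVolume


@pytest.fixture()
def grid16() -> GridSpec:
    return GridSpec.create((16, 16, 16))


@pytest.fixture()
def grid64() -> GridSpec:
    return ph.default_grid()


def random_mask(grid: GridSpec, rng: np.random.Generator,
                p: float = 0.3) -> MaskVolume:
    return MaskVolume(grid, rng.random(grid.shape) < p)


@pytest.fixture(scope="session")
def displacement_case() -> ph.PhantomCase:
    """Meningioma-like phantom shared across the suite (8 mm push)."""
    return ph.default_displacement_case(8.0, rng_seed=3)


@pytest.fixture(scope="session")
def null_case() -> ph.PhantomCase:
    """Perfectly mirror-symmetric case: infiltration with fraction 0."""
    return ph.default_infiltration_case(0.0, rng_seed=1)


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()
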