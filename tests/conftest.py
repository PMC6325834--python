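import numpy as np
import pytest

from abdomct import CTVolume
from abdomct.synthetic_data import default_phantom_spec, generate_phantom


def make_random_volume(seed: int, shape=(6, 6, 5), spacing=(1.0, 1.0, 1.0)) -> CTVolume:
    """Small seeded random HU volume spanning air through dense bone."""
    rng = np.random.default_rng(seed)
    vox = rng.integers(-1024, 3001, size=shape).astype(np.int16)
    return CTVolume(voxels=vox, spacing=spacing)


@pytest.fixture
def random_volume():
    return make_random_volume(seed=42, shape=(8, 8, 6))


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = default_phantom_spec(seed=0)
    spec = type(spec)(
        **{
            **{f: getattr(spec, f) for f in spec.__dataclass_fields__},
            "hu_params": {"fat": (-100.0, 0.0), "lean": (60.0, 0.0), "bone": (700.0, 0.0)},
        }
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(default_phantom_spec(seed=7))
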