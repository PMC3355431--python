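import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quatpalm import QuaternionArray, SynthConfig, generate_dataset

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def rand_quaternion_array(rng, shape):
    return QuaternionArray(*rng.normal(size=(4,) + tuple(shape)))


def rand_hermitian(rng, n):
    A = rand_quaternion_array(rng, (n, n))
    return (A + A.H) * 0.5


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth():
    """Small, easy synthetic dataset shared across tests: 6 palms, 64px bands."""
    cfg = SynthConfig(n_classes=6, instances_per_class=6, image_size=64, seed=42)
    gallery, probe = generate_dataset(cfg)
    return cfg, gallery, probe


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, small_synth):
    """The small synthetic set written out in the PNG + manifest layout."""
    from quatpalm import write_dataset

    _, gallery, probe = small_synth
    root = tmp_path_factory.mktemp("synth_ds")
    write_dataset(gallery, root / "gallery")
    write_dataset(probe, root / "probe")
    return root
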