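import numpy as np
import pytest

from petcycle import LesionSpec, PETVolume, PhantomSpec, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume_pair(rng):
    """A random but valid LD/FD volume pair on a 12x12x4 grid."""
    fd = PETVolume(rng.random((12, 12, 4)) * 40.0, domain_role="full_dose")
    ld = PETVolume(
        np.clip(fd.values + rng.normal(0, 5.0, fd.shape), 0, None),
        domain_role="low_dose",
    )
    return ld, fd


def smoke_phantom_spec() -> PhantomSpec:
    """16x16x8 phantom with one central lesion: the scaled-down test scene."""
    return PhantomSpec(
        grid_dims=(16, 16, 8),
        background_kbq_ml=30.0,
        lesions=[LesionSpec((8, 8, 4), 310.0, 91.12, label="central")],
    )


def smoke_pair(seed: int, dose: float = 0.1):
    return generate_pair(
        smoke_phantom_spec(),
        dose_fraction=dose,
        count_budget=4000,
        n_iter=10,
        seed=seed,
        n_angles=24,
    )
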