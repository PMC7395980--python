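import numpy as np
import pytest

from mvsir.labeling import CenterSample
from mvsir.phantom import PhantomParams, generate_phantom
from mvsir.preprocess import NoduleCube, consensus_mask, extract_cube


@pytest.fixture(scope="session")
def clean_params() -> PhantomParams:
    """Noise- and jitter-free phantom: geometry checks need exact consistency."""
    return PhantomParams(noise_sigma=0.0, reader_jitter=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_case(clean_params):
    return generate_phantom(clean_params)


@pytest.fixture(scope="session")
def noisy_case():
    return generate_phantom(PhantomParams(seed=11))


@pytest.fixture(scope="session")
def clean_cube(clean_case, clean_params) -> NoduleCube:
    cons = consensus_mask(clean_case.annotations, clean_case.volume.shape,
                          n_readers=clean_params.n_readers)
    return extract_cube(clean_case.volume, cons, pad=10)


@pytest.fixture
def small_cube() -> NoduleCube:
    """Tiny hand-made cube: ramp intensities, centred 3x5x5 box mask."""
    data = np.arange(9 * 11 * 11, dtype=float).reshape(9, 11, 11)
    mask = np.zeros((9, 11, 11), dtype=bool)
    mask[3:6, 3:8, 3:8] = True
    return NoduleCube(data, mask, pad=0, offset=(0, 0, 0))


def make_centers(*triples):
    return [CenterSample(t, lab, t[0]) for t, lab in triples]
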