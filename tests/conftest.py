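import dataclasses

import numpy as np
import pytest

from dxafemur.phantom import PhantomSpec, make_dataset, make_phantom, simulate_scan


@pytest.fixture(scope="session")
def clean_spec():
    """Default 128x128 phantom spec with noise disabled."""
    return dataclasses.replace(PhantomSpec.default(), noise="none")


@pytest.fixture(scope="session")
def noisy_spec():
    """Default 128x128 phantom spec with Poisson count noise."""
    return PhantomSpec.default()


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    """One noise-free (scan, truth) pair, fixed seed."""
    rng = np.random.default_rng(42)
    truth = make_phantom(clean_spec, rng)
    scan = simulate_scan(truth, clean_spec, rng)
    return scan, truth


@pytest.fixture(scope="session")
def noisy_phantom(noisy_spec):
    """One Poisson-noise (scan, truth) pair, fixed seed."""
    rng = np.random.default_rng(42)
    truth = make_phantom(noisy_spec, rng)
    scan = simulate_scan(truth, noisy_spec, rng)
    return scan, truth


@pytest.fixture(scope="session")
def clean_dataset(clean_spec):
    """Ten noise-free phantoms with jittered geometry."""
    return make_dataset(10, clean_spec, seed=1)
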