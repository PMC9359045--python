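import numpy as np
import pytest

from hdaunet.phantom import PhantomSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_case():
    """One deterministic 24x24x16 phantom case shared across tests."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 16),
        seed=42,
        n_oars=2,
        ptv_radius_range=(5.0, 8.0),
        oar_radius_range=(2.0, 4.0),
    )
    return generate_cohort(spec, 1)[0]


@pytest.fixture(scope="session")
def default_cohort():
    """A 20-case cohort at the default generator settings."""
    return generate_cohort(PhantomSpec(seed=11), 20)


def fd_gradient(fn, tensor, indices, eps=1e-6):
    """Central finite-difference gradient of scalar ``fn`` at flat ``indices``."""
    flat = tensor.data.reshape(-1)
    grads = []
    for i in indices:
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn()
        flat[i] = orig - eps
        fm = fn()
        flat[i] = orig
        grads.append((fp - fm) / (2 * eps))
    return np.asarray(grads)
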