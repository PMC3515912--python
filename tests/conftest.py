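import numpy as np
import pytest

import lungreg as lr


def small_phantom_spec(seed: int = 1) -> lr.PhantomSpec:
    """32^3 phantom whose finest vessel generation is about one voxel wide."""
    return lr.PhantomSpec(
        shape=(32, 32, 32),
        lung_semiaxes=(11.0, 12.0, 13.0),
        root_radius=1.8,
        root_length=8.0,
        truth_grid_spacing=8.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def phantom32():
    """Small phantom pair shared across tests (read-only)."""
    return lr.generate_phantom_pair(small_phantom_spec(1), seed=1)


@pytest.fixture(scope="session")
def phantom64():
    """Full-size phantom: 64^3, 1 mm voxels, noise 5 HU, amplitude 0.5."""
    return lr.generate_phantom_pair(lr.PhantomSpec(), seed=1)


@pytest.fixture(scope="session")
def recovery64(phantom64):
    """SSTVD + SSVMD registration of the 64^3 phantom (chi=1, gamma=0.1)."""
    from lungreg.registration import (
        RegistrationConfig,
        build_phantom_schedule,
        register,
    )

    cfg = RegistrationConfig(
        metric="sstvd",
        weights=lr.CostWeights(chi=1.0, gamma_reg=0.1),
        schedule=build_phantom_schedule(),
    )
    return register(phantom64, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def bounded_random_transform(domain_vol, grid_spacing, seed, fraction=1.0):
    """Random transform with coefficients within fraction * delta/K."""
    T = lr.BSplineTransform.for_volume(domain_vol, np.full(3, float(grid_spacing)))
    bound = fraction * lr.injectivity_bounds(T)
    gen = np.random.default_rng(seed)
    T.coefficients = gen.uniform(-bound, bound, T.coefficients.shape)
    return T
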