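import numpy as np
import pytest

from msiroi.cubes import HFCube, MSICube
from msiroi.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def phantom_default():
    """Default phantom: K_true=4, 60x60 grid, 2 px deformation."""
    return generate_phantom(PhantomParams(), seed=0)


@pytest.fixture(scope="session")
def phantom_clean():
    """Noise-free, deformation-free phantom: both modalities share one
    pixel-exact ground truth."""
    params = PhantomParams(msi_noise=0.0, hf_noise=0.0, hf_smooth=0.0,
                           tic_cv=0.0, saltpepper_rate=0.0,
                           deformation_px=0.0)
    return generate_phantom(params, seed=0)


@pytest.fixture(scope="session")
def phantom_warped():
    """Phantom with a serial-section-style mismatch: 3 px offset plus a
    mild smooth warp."""
    params = PhantomParams(deformation_px=1.0, translation_px=(3.0, 0.0))
    return generate_phantom(params, seed=0)


@pytest.fixture()
def tiny_msi_cube():
    """3x3 cube with 4 channels and a simple deterministic fill."""
    rng = np.random.default_rng(42)
    inten = rng.uniform(0.1, 5.0, (3, 3, 4))
    return MSICube((3, 3), 100.0, [100.0, 200.0, 300.0, 400.0], inten,
                   np.ones((3, 3), dtype=bool), {"fixture": "tiny"})


@pytest.fixture()
def tiny_hf_cube():
    rng = np.random.default_rng(7)
    feats = rng.uniform(0.0, 1.0, (4, 5, 6))
    mask = np.ones((4, 5), dtype=bool)
    mask[0, 0] = False
    feats[0, 0] = 0.0
    return HFCube((4, 5), 200, feats, mask, {"backend": "test"})
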