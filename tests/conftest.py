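import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import oxyflow as ox


@pytest.fixture(scope="session")
def paradigm():
    return ox.Paradigm()  # 40/20/60 s at 1 Hz


@pytest.fixture(scope="session")
def textured_frame():
    """Smoothed random texture: a generic frame for registration tests."""
    rng = np.random.default_rng(42)
    return gaussian_filter(rng.random((64, 64)), 2)


@pytest.fixture(scope="session")
def control_bundle():
    """Small noise-free control scene rendered once for the session."""
    scene = ox.control_scene(shape=(64, 64), noise_sd=0.0)
    stack, cal, masks, truth = ox.render_stack(scene, seed=11)
    return scene, stack, cal, masks, truth


@pytest.fixture(scope="session")
def control_maps(control_bundle):
    _, stack, cal, _, _ = control_bundle
    return ox.compute_hemodynamics(stack, cal)
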