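import dataclasses

import numpy as np
import pytest

from vesselmotion.phantom import (
    EnhancementModel,
    LinearDrift,
    PhantomConfig,
    _suite_configs,
    generate,
)


@pytest.fixture(scope="session")
def suite():
    """The default phantom fixture suite, generated once per session."""
    return {name: generate(cfg) for name, cfg in _suite_configs(0).items()}


def gaussian_blob(center, sigma=4.0, amplitude=300.0, shape=(64, 64)):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


@pytest.fixture
def small_drift_phantom():
    """Small vessel (5 mm) drifting 1 px/frame at constant enhancement.

    Small enough that per-pair flow recovery supports integer ROI tracking.
    """
    cfg = PhantomConfig(
        frame_shape=(96, 96),
        n_frames=8,
        vessel_radius_mm=5.0,
        vessel_center0=(30.0, 48.0),
        trajectory=LinearDrift(drow_px=1.0),
        enhancement=EnhancementModel(baseline_hu=200.0, plateau_hu=200.0),
        noise_sd=0.0,
        seed=0,
    )
    return generate(cfg)


@pytest.fixture
def static_phantom():
    cfg = dataclasses.replace(_suite_configs(0)["static"], noise_sd=0.0)
    return generate(cfg)
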