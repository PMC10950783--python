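import math

import numpy as np
import pytest

from nanoturbine import synth


@pytest.fixture
def acq_default() -> synth.AcquisitionParams:
    """Standard acquisition: 200 fps, 8,000 frames, 15 nm noise."""
    return synth.AcquisitionParams()


@pytest.fixture
def acq_clean() -> synth.AcquisitionParams:
    """Noise-free, lossless acquisition for exactness tests."""
    return synth.AcquisitionParams(loc_noise_sigma=0.0, detection_prob=1.0)


def make_rotor_locs(
    omega_rev: float = 5.0,
    D_r: float = 0.5,
    seed: int = 42,
    acq: synth.AcquisitionParams | None = None,
    **truth_kwargs,
):
    truth = synth.RotorTruth(omega_d=2 * math.pi * omega_rev, D_r=D_r, **truth_kwargs)
    return synth.simulate_rotor(truth, acq or synth.AcquisitionParams(), seed), truth


@pytest.fixture
def rotor_dataset(acq_default):
    """One driven rotor at the standard conditions, with its truth."""
    return make_rotor_locs(acq=acq_default)


def circle_points(n: int, radius: float, center=(0.0, 0.0), rng=None, noise=0.0):
    rng = rng or np.random.default_rng(0)
    th = rng.uniform(0, 2 * np.pi, n)
    pts = np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )
    if noise:
        pts += noise * rng.standard_normal(pts.shape)
    return pts
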