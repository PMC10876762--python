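"""Shared fixtures: small synthetic phantoms sized for fast unit tests."""

import numpy as np
import pytest

import fastptx as fp


@pytest.fixture(scope="session")
def maps8():
    """8-channel 12^3 head phantom (18 mm voxels), the workhorse fixture."""
    return fp.synth_fieldmaps(
        fp.PhantomSpec(n_channels=8, grid_shape=(12, 12, 12), resolution=0.018, seed=0)
    )


@pytest.fixture(scope="session")
def maps2_tiny():
    """2-channel 3^3 phantom for finite-difference gradient checks."""
    return fp.synth_fieldmaps(
        fp.PhantomSpec(n_channels=2, grid_shape=(3, 3, 3), resolution=0.06,
                       b0_range=150.0, seed=3)
    )


@pytest.fixture(scope="session")
def vops8():
    """Five synthetic 8-channel SAR matrices."""
    return fp.synth_vops(5, 8, seed=1)


@pytest.fixture(scope="session")
def cp10_8(maps8):
    """CP-mode rectangular pulse scaled to a 10 deg mean FA on maps8."""
    cp = fp.cp_mode_pulse(8, 1.0, 520e-6, 1e-5)
    return fp.scale_pulse_to_mean_fa(cp, maps8, 10.0, model="sta")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
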