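import numpy as np
import pytest

from tfparam.synthgen import (BurstSpec, EvokedSpec, SyntheticDesign,
                              default_channel_positions)


@pytest.fixture(scope="session")
def positions32():
    return default_channel_positions()


@pytest.fixture(scope="session")
def small_positions(positions32):
    """Six well-separated channels for fast statistics tests."""
    return positions32[[4, 8, 13, 19, 22, 30]]  # Fz, FC5, Cz, CP6, Pz, O1


def make_single_condition_design(positions, n_trials=100, seed=0, **kwargs) -> SyntheticDesign:
    """One-condition design with a plain 1/f background; components via kwargs."""
    base = dict(
        n_subjects=4, n_trials_per_condition=n_trials,
        channel_positions=positions, conditions=("stim",),
        aperiodic_offset={"stim": -1.0}, aperiodic_exponent={"stim": 1.0},
        evoked=EvokedSpec(amplitude_uv=0.0), seed=seed,
    )
    base.update(kwargs)
    return SyntheticDesign(**base)


@pytest.fixture()
def theta_burst_design(small_positions):
    """Single condition: 1/f background plus an induced 6-Hz post-stimulus burst."""
    return make_single_condition_design(
        small_positions[:2], n_trials=100, seed=3,
        bursts=(BurstSpec(6.0, 2.0, 400.0, 150.0, "stim"),))
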