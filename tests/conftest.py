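import numpy as np
import pytest

from rsomqc import synthetic_rsom as syn
from rsomqc.data_model import MotionGraph, SystemConfig


@pytest.fixture
def small_config():
    """Tiny geometry for fast unit tests."""
    return SystemConfig(n_fast=8, n_slow=4, focal_depth=240.0)


@pytest.fixture
def std_config():
    """The desk-scale 64 x 16 geometry used throughout the suite."""
    return syn.standard_config()


@pytest.fixture
def std_phantom():
    return syn.standard_phantom()


@pytest.fixture
def flat_phantom():
    """Flat melanin surface at 150 um, no vessels."""
    return syn.PhantomSpec(surface_mean_depth=150.0, surface_tilt=(0.0, 0.0),
                           surface_amplitude=1.0)


def physiological_motion(config: SystemConfig, target_std: float,
                         seed: int = 0) -> MotionGraph:
    """Standard pulse-dominated motion normalized to a target std, covering
    one scan duration at the A-line rate."""
    base = syn.make_base_motion(syn.standard_motion_spec(seed=seed),
                                duration=config.scan_duration + 1.0 / config.pulse_rate,
                                dt=1.0 / config.pulse_rate)
    return syn.normalize_motion(base, target_std)


@pytest.fixture
def make_motion():
    return physiological_motion
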