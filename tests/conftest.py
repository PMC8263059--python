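"""Shared fixtures: a handful of session-scoped synthetic recordings so the
expensive 100 Hz simulations are generated once per run."""

import numpy as np
import pytest

import b63osc as b


@pytest.fixture(scope="session")
def asw_trace():
    """Default control recording (600 s, seed 0) with its ground truth."""
    return b.generate_cell_trace(b.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def long_asw_trace():
    """Longer control recording (1200 s, seed 11) for event statistics."""
    return b.generate_cell_trace(b.GeneratorConfig(seed=11, duration_s=1200.0))


@pytest.fixture(scope="session")
def clean_sine_1hz():
    """Pure 61 s sinusoid at 1 Hz, 1800 s: exact spectral ground truth."""
    t = np.arange(1800.0)
    v = -60.0 + 5.0 * np.sin(2.0 * np.pi * t / 61.0)
    return b.VoltageTrace(0.0, 1.0, v)
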