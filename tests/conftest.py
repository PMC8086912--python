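import numpy as np
import pytest

from segdyn import ModelConfig, preset, run


@pytest.fixture(scope="session")
def clock_timer_history():
    """Default temporal clock+timer run, shared across read-only tests."""
    return run(preset("clock_timer_temporal"))


@pytest.fixture(scope="session")
def clock_timer_spatial_history():
    return run(preset("clock_timer_spatial"))


@pytest.fixture(scope="session")
def growth_history():
    return run(preset("three_timers_growth"))


@pytest.fixture()
def tiny_config():
    """A config small enough for step-by-step inspection."""
    return ModelConfig(variant="clock_timer", T1=10.0, P=5.0, v=0.5, r=2, steps=60)
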