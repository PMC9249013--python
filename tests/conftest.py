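import numpy as np
import pytest
from hypothesis import settings

import cisync as cs

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def fb22():
    """Standard 22-channel filterbank at the default sample rate."""
    return cs.design_filterbank(22, 125.0, 8000.0, 100_000.0)


@pytest.fixture(scope="session")
def tone500():
    return cs.make_pure_tone(500.0, 0.030, 100_000.0)


@pytest.fixture(scope="session")
def ch500(tone500, fb22):
    return cs.apply_filterbank(tone500, fb22)


@pytest.fixture(scope="session")
def hdcis500(ch500):
    return cs.schedule_carrier(cs.hdcis_envelopes(ch500), strategy="hdcis")


@pytest.fixture(scope="session")
def cis500(ch500):
    return cs.schedule_carrier(cs.cis_envelopes(ch500), strategy="cis")


@pytest.fixture(scope="session")
def pdt500(ch500):
    return cs.pdt_encode(ch500)


@pytest.fixture(scope="session")
def single_pulse_traces():
    """A lone 1 mA biphasic pulse delivered directly at one position."""
    from cisync.current_spread import FieldTraceSet
    from cisync.strategies import PulseParams

    return FieldTraceSet(
        positions_mm=np.array([0.0]),
        pulse_times_us=np.array([1000.0]),
        eff_amplitudes_ma=np.array([[1.0]]),
        params=PulseParams(),
        duration_us=2000.0,
    )
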