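import logging

import pytest

import vdacgate as vg

# analysis warnings (few measurements, fallbacks) are expected on the small
# fixtures used here
logging.getLogger("vdacgate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def native():
    return vg.build_preset("native")


@pytest.fixture(scope="session")
def quiet_native(native):
    """Native preset with noise and conductance jitter switched off."""
    return native.with_(noise_sd_pA=0.0, conductance_jitter_sd_nS=0.0)


@pytest.fixture(scope="session")
def step_protocol():
    """10 s steps over +-10, +-20, +-40 mV (60 s total)."""
    return vg.VoltageProtocol(tuple((10.0, v) for v in (10, -10, 20, -20, 40, -40)))


@pytest.fixture(scope="session")
def native_trace_decimated(native, step_protocol):
    """One noisy native recording at 5 kHz decimated to 200 Hz."""
    return vg.simulate_trace(native, step_protocol, fs_Hz=5000.0, seed=1,
                             insertion_s=1.0, decimate_to_Hz=200.0)
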