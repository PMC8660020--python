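import pytest

from natalmap.sweeps import StepProtocol
from natalmap.synth import NeuronParams, PscSimParams, simulate_current_clamp, simulate_psc_trace

DT = 1e-4  # 10 kHz acquisition grid


@pytest.fixture(scope="session")
def passive_params() -> NeuronParams:
    return NeuronParams(v_rest=-65.0, r_m=100.0, c_m=200.0, g_h=0.0)


@pytest.fixture(scope="session")
def ih_params() -> NeuronParams:
    return NeuronParams(v_rest=-65.0, r_m=100.0, c_m=200.0, g_h=2.0, e_h=-30.0)


@pytest.fixture(scope="session")
def subthreshold_protocol() -> StepProtocol:
    return StepProtocol(step_onset=0.2, step_duration=0.5,
                        amplitudes=tuple(float(a) for a in range(-100, 0, 20)),
                        baseline_window=(0.0, 0.2))


@pytest.fixture(scope="session")
def sag_protocol() -> StepProtocol:
    return StepProtocol(step_onset=0.2, step_duration=1.0, amplitudes=(-200.0,),
                        baseline_window=(0.0, 0.2))


@pytest.fixture(scope="session")
def passive_sweeps(passive_params, subthreshold_protocol):
    return simulate_current_clamp(passive_params, subthreshold_protocol, dt=DT)


@pytest.fixture(scope="session")
def ih_sag_sweeps(ih_params, sag_protocol):
    return simulate_current_clamp(ih_params, sag_protocol, dt=DT)


@pytest.fixture(scope="session")
def clean_psc():
    """Noiseless sparse PSC trace with known kernel (tau_r 0.5, tau_d 5 ms)."""
    params = PscSimParams(rate=0.5, amp_mean=50.0, amp_sd=0.0, tau_rise=0.5,
                          tau_decay=5.0, noise_sd=0.0, duration=20.0)
    sweeps, events = simulate_psc_trace(params, seed=11)
    return params, sweeps, events
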