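import numpy as np
import pytest

from striatype import AdExParams, StepProtocol, simulate_adex


@pytest.fixture(scope="session")
def passive_params() -> AdExParams:
    """Non-spiking cell: tiny Delta_T and a threshold far above reach."""
    return AdExParams(
        C=150.0, g_L=10.0, E_L=-80.0, V_T=0.0, Delta_T=0.5, a=0.0, b=0.0,
        V_reset=-60.0, V_cut=20.0,
    )


@pytest.fixture(scope="session")
def passive_recording(passive_params):
    """Noise-free passive recording on the default step protocol."""
    return simulate_adex(passive_params, StepProtocol(), noise_sd=0.0, seed=0)


def scalar_adex_reference(p, I_amp, protocol, dt_ms):
    """Independent scalar Euler integration of the AdEx equations.

    Deliberately written as a plain per-step loop, separate from the
    package's vectorized integrator, for use as a refined-step oracle.
    """
    import math

    t_on = protocol.pre_stim * 1000.0
    t_off = (protocol.pre_stim + protocol.pulse_dur) * 1000.0
    n = int(round(protocol.total_dur * 1000.0 / dt_ms))
    V, w = p.E_L, 0.0
    cap = (p.V_cut - p.V_T) / p.Delta_T
    spikes = []
    trace = []
    for j in range(n):
        t = j * dt_ms
        trace.append(V)
        I = I_amp if t_on <= t < t_off else 0.0
        ex = p.g_L * p.Delta_T * math.exp(min((V - p.V_T) / p.Delta_T, cap))
        dV = (-p.g_L * (V - p.E_L) + ex - w + I) / p.C
        dw = (p.a * (V - p.E_L) - w) / p.tau_w
        V += dt_ms * dV
        w += dt_ms * dw
        if V >= p.V_cut:
            spikes.append((j + 1) * dt_ms / 1000.0)
            V = p.V_reset
            w += p.b
    return np.array(spikes), np.array(trace)


@pytest.fixture(scope="session")
def adex_reference():
    return scalar_adex_reference
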