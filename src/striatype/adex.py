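"""Adaptive-exponential integrate-and-fire (AdEx) simulator.

Ground-truth generator for the feature-extraction pipeline: each simulated
cell runs the standard current-step protocol and returns a
:class:`~striatype.recording.Recording` whose true parameters and spike times
are known, so extraction accuracy can be scored exactly.

Model (Brette & Gerstner 2005), in the package's unit system
(mV, pA, pF, nS, ms)::

    C dV/dt = -g_L (V - E_L) + g_L * Delta_T * exp((V - V_T)/Delta_T) - w + I
    tau_w dw/dt = a (V - E_L) - w

with a reset rule: when V reaches ``V_cut`` a spike is registered, the sample
at the spike time is written as a peak marker at ``V_cut`` (so spike
detection has a peak to find), V is reset to ``V_reset`` and w increments by
``b``.  Integration is fixed-step explicit Euler at 0.05 ms (or finer when
the sampling interval requires it); the exponential argument is clipped at
the cut value so the blow-up step cannot overflow.

Three illustrative presets ship with the package (``msn``, ``thin``,
``fan``): a hyperpolarized high-rheobase projection-neuron-like cell, a
depolarized low-rheobase interneuron-like cell, and a strongly adapting
cell.  They are qualitative phenotypes, not fits to published per-type
measurements.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .exceptions import SimulationError, ValidationError
from .recording import Recording, StepProtocol, Sweep

__all__ = [
    "AdExParams",
    "simulate_adex",
    "simulate_population",
    "load_presets",
    "preset",
    "jittered_params",
]

#: Default integration step (ms); the integrator never uses a coarser step.
DEFAULT_DT_MS = 0.05


@dataclass(frozen=True)
class AdExParams:
    """AdEx model parameters for one cell."""

    C: float = 100.0  # pF
    g_L: float = 10.0  # nS
    E_L: float = -70.0  # mV
    V_T: float = -50.0  # mV
    Delta_T: float = 2.0  # mV
    a: float = 0.0  # nS, subthreshold adaptation conductance
    tau_w: float = 100.0  # ms
    b: float = 0.0  # pA, spike-triggered adaptation increment
    V_reset: float = -60.0  # mV
    V_cut: float = 20.0  # mV, detection ceiling / peak marker

    def __post_init__(self) -> None:
        if min(self.C, self.g_L, self.tau_w) <= 0:
            raise ValidationError("C, g_L and tau_w must be positive")
        if self.Delta_T <= 0:
            raise ValidationError("Delta_T must be positive")
        if self.V_reset >= self.V_cut:
            raise ValidationError("V_reset must lie below V_cut")

    @property
    def input_resistance_mohm(self) -> float:
        """Passive input resistance 1/g_L in MOhm."""
        return 1000.0 / self.g_L

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant C/g_L in ms."""
        return self.C / self.g_L


def _integrate_batch(
    params: list[AdExParams],
    stimuli: np.ndarray,
    protocol: StepProtocol,
    dt_ms: float,
) -> tuple[np.ndarray, list[list[float]]]:
    """Euler-integrate a batch of (cell, step-amplitude) pairs in lockstep.

    Returns the decimated voltage matrix (batch x n_samples, mV) and the
    spike times (s) per batch element.  ``params[i]`` drives ``stimuli[i]``.
    """
    B = len(params)
    sample_int_ms = 1000.0 / protocol.sampling_rate
    k = max(1, int(np.ceil(sample_int_ms / dt_ms - 1e-12)))
    dt = sample_int_ms / k  # exact integer decimation
    n_samples = protocol.n_samples
    n_steps = n_samples * k

    arr = lambda name: np.array([getattr(p, name) for p in params], dtype=float)
    C, g_L, E_L = arr("C"), arr("g_L"), arr("E_L")
    V_T, Delta_T, a = arr("V_T"), arr("Delta_T"), arr("a")
    tau_w, b, V_reset, V_cut = arr("tau_w"), arr("b"), arr("V_reset"), arr("V_cut")
    exp_cap = (V_cut - V_T) / Delta_T  # exponential argument never exceeds this

    I_amp = np.asarray(stimuli, dtype=float)
    t_on = protocol.pre_stim * 1000.0
    t_off = (protocol.pre_stim + protocol.pulse_dur) * 1000.0

    V = E_L.copy()
    w = np.zeros(B)
    out = np.empty((B, n_samples))
    spikes: list[list[float]] = [[] for _ in range(B)]

    for j in range(n_steps):
        if j % k == 0:
            out[:, j // k] = V
        t = j * dt
        I = I_amp if t_on <= t < t_off else 0.0
        expterm = Delta_T * np.exp(np.minimum((V - V_T) / Delta_T, exp_cap))
        dV = (-g_L * (V - E_L) + g_L * expterm - w + I) / C
        dw = (a * (V - E_L) - w) / tau_w
        V = V + dt * dV
        w = w + dt * dw
        fired = V >= V_cut
        if fired.any():
            t_spike = (j + 1) * dt
            for idx in np.nonzero(fired)[0]:
                spikes[idx].append(t_spike / 1000.0)
            V = np.where(fired, V_reset, V)
            w = np.where(fired, w + b, w)
        if not np.all(np.isfinite(V)):
            bad = int(np.nonzero(~np.isfinite(V))[0][0])
            raise SimulationError(
                f"non-finite membrane potential at t={t:.3f} ms for "
                f"stimulus {I_amp[bad]} pA"
            )

    # Stamp peak markers at the recorded sample nearest each spike time.
    for idx, times in enumerate(spikes):
        for ts in times:
            si = min(n_samples - 1, int(round(ts * 1000.0 / sample_int_ms)))
            out[idx, si] = V_cut[idx]
    return out, spikes


def simulate_adex(
    params: AdExParams,
    protocol: StepProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_ms: float = DEFAULT_DT_MS,
    cell_id: str = "sim",
    series_resistance: float = 10.0,
) -> Recording:
    """Simulate one cell through the full step protocol.

    Deterministic for a fixed seed.  Measurement noise (``noise_sd`` mV,
    additive white Gaussian) is applied to the recorded samples, not to the
    dynamics.  Ground-truth spike times per sweep are stored in
    ``Recording.metadata["spike_times"]``.
    """
    if dt_ms > DEFAULT_DT_MS + 1e-12:
        raise ValidationError(f"integration step must be <= {DEFAULT_DT_MS} ms")
    protocol = protocol or StepProtocol()
    stimuli = np.array(protocol.step_amplitudes)
    plist = [params] * len(stimuli)
    out, spikes = _integrate_batch(plist, stimuli, protocol, dt_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.shape)
    sweeps = [
        Sweep(stimulus=float(s), samples=out[i], dt=protocol.dt)
        for i, s in enumerate(stimuli)
    ]
    return Recording(
        cell_id=cell_id,
        protocol=protocol,
        sweeps=sweeps,
        series_resistance=series_resistance,
        metadata={
            "generator": "adex",
            "params": {k: getattr(params, k) for k in AdExParams.__dataclass_fields__},
            "noise_sd": noise_sd,
            "seed": seed,
            "spike_times": {str(float(s)): spikes[i] for i, s in enumerate(stimuli)},
        },
    )


def simulate_population(
    params_list: list[AdExParams],
    protocol: StepProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_ids: list[str] | None = None,
    dt_ms: float = DEFAULT_DT_MS,
) -> list[Recording]:
    """Simulate many cells in one vectorized pass (batched over cell x step)."""
    protocol = protocol or StepProtocol()
    n_steps = len(protocol.step_amplitudes)
    flat_params: list[AdExParams] = []
    flat_stim: list[float] = []
    for p in params_list:
        flat_params.extend([p] * n_steps)
        flat_stim.extend(protocol.step_amplitudes)
    out, spikes = _integrate_batch(flat_params, np.array(flat_stim), protocol, dt_ms)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, out.shape)
    recs = []
    for ci, p in enumerate(params_list):
        rows = slice(ci * n_steps, (ci + 1) * n_steps)
        sweeps = [
            Sweep(stimulus=float(s), samples=out[rows][i], dt=protocol.dt)
            for i, s in enumerate(protocol.step_amplitudes)
        ]
        recs.append(
            Recording(
                cell_id=cell_ids[ci] if cell_ids else f"sim{ci:03d}",
                protocol=protocol,
                sweeps=sweeps,
                series_resistance=10.0,
                metadata={
                    "generator": "adex",
                    "params": {k: getattr(p, k) for k in AdExParams.__dataclass_fields__},
                    "noise_sd": noise_sd,
                    "seed": seed,
                    "spike_times": {
                        str(float(s)): spikes[ci * n_steps + i]
                        for i, s in enumerate(protocol.step_amplitudes)
                    },
                },
            )
        )
    return recs


def load_presets() -> dict[str, AdExParams]:
    """Load the shipped illustrative cell-type presets from YAML."""
    text = (
        importlib.resources.files("striatype") / "presets" / "adex.yaml"
    ).read_text()
    raw = yaml.safe_load(text)
    return {name: AdExParams(**vals) for name, vals in raw.items()}


def preset(name: str) -> AdExParams:
    presets = load_presets()
    try:
        return presets[name.lower()]
    except KeyError:
        raise ValidationError(
            f"unknown preset '{name}' (available: {sorted(presets)})"
        ) from None


def jittered_params(
    base: AdExParams, rng: np.random.Generator, rel_sd: float = 0.08
) -> AdExParams:
    """Cell-to-cell variability: multiplicative jitter on passive parameters,
    additive jitter (1.5 mV SD) on the leak reversal."""
    f = lambda: float(np.exp(rng.normal(0.0, rel_sd)))
    return replace(
        base,
        C=base.C * f(),
        g_L=base.g_L * f(),
        E_L=base.E_L + float(rng.normal(0.0, 1.5)),
        b=base.b * f(),
    )
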