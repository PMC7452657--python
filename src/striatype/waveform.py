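"""Piecewise-linear action-potential composer.

Builds voltage traces whose spike kinetics (amplitude, half-width, AHP,
maximum rise/fall slopes, adaptation ratios) are known in closed form, for
validating the feature-extraction code sample-by-sample.

During the current pulse the trace sits on a depolarized inter-spike
plateau between the AHP trough and threshold, as a real cell does under
sustained suprathreshold current; outside the pulse it rests at baseline.
Each action potential is a piecewise-linear template anchored at its
threshold-crossing time: a slow lead ramp from the plateau to threshold
(slope kept below the spike-detection criterion), a linear rise to the
peak, a linear fall back to threshold, a V-shaped afterhyperpolarization to
``threshold - ahp_depth`` and back to the plateau.  With this shape the
true half-width is exactly ``(rise_time + fall_time) / 2`` and the true AHP
amplitude (threshold to trough) is exactly ``ahp_depth``, since the plateau
keeps the trough a strict local minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SpecError
from .recording import Recording, StepProtocol, Sweep

__all__ = ["WaveformSpec", "compose_waveform"]


@dataclass(frozen=True)
class WaveformSpec:
    """Analytic description of a spike train on a flat baseline."""

    baseline: float = -70.0  # mV
    ap_times: tuple[float, ...] = (0.5,)  # s, threshold-crossing times
    ap_threshold: float = -40.0  # mV
    ap_peaks: tuple[float, ...] = (40.0,)  # mV, one per AP
    rise_time: float = 1.0  # ms
    fall_time: float = 1.0  # ms
    ahp_depth: float = 10.0  # mV below threshold
    ahp_dur: float = 20.0  # ms, trough + recovery
    lead_time: float = 3.0  # ms, sub-criterion ramp plateau -> threshold
    pulse_plateau: float | None = None  # mV; inter-spike level, default midway
    onset_ramp: float = 10.0  # ms, baseline -> plateau at pulse start

    def __post_init__(self) -> None:
        if self.pulse_plateau is None:
            # Depolarized inter-spike level: between the AHP trough and
            # threshold, so the trough is a genuine local minimum.
            object.__setattr__(
                self, "pulse_plateau", self.ap_threshold - self.ahp_depth / 2.0
            )
        times = tuple(float(t) for t in self.ap_times)
        peaks = tuple(float(p) for p in self.ap_peaks)
        object.__setattr__(self, "ap_times", times)
        object.__setattr__(self, "ap_peaks", peaks)
        if len(times) != len(peaks):
            raise SpecError("need one peak per AP time")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise SpecError("ap_times must be strictly increasing")
        if not all(p > self.ap_threshold for p in peaks):
            raise SpecError("every peak must exceed the threshold")
        if self.ap_threshold <= self.baseline:
            raise SpecError("threshold must lie above baseline")
        trough = self.ap_threshold - self.ahp_depth
        if not trough < self.pulse_plateau < self.ap_threshold:
            raise SpecError(
                "pulse_plateau must lie between the AHP trough "
                f"({trough} mV) and the threshold ({self.ap_threshold} mV)"
            )
        footprint_s = (self.rise_time + self.fall_time + self.ahp_dur) / 1000.0
        for t0, t1 in zip(times, times[1:]):
            if t1 - t0 < footprint_s:
                raise SpecError(
                    f"APs at {t0} s and {t1} s overlap "
                    f"(spacing < rise+fall+ahp_dur = {footprint_s * 1e3:.1f} ms)"
                )

    # ---- closed-form ground truths -------------------------------------
    def true_amplitudes(self) -> list[float]:
        """Threshold-to-peak amplitude per AP (mV)."""
        return [p - self.ap_threshold for p in self.ap_peaks]

    @property
    def true_half_width(self) -> float:
        """Width at the threshold/peak midpoint (ms); linear flanks."""
        return (self.rise_time + self.fall_time) / 2.0

    @property
    def true_ahp_amplitude(self) -> float:
        return self.ahp_depth

    def true_max_rise(self, ap: int = 0) -> float:
        """mV/ms on the rising flank of AP ``ap``."""
        return (self.ap_peaks[ap] - self.ap_threshold) / self.rise_time

    def true_max_fall(self, ap: int = 0) -> float:
        """Magnitude of the falling-flank slope (mV/ms)."""
        return (self.ap_peaks[ap] - self.ap_threshold) / self.fall_time

    def true_amp_adaptation(self) -> float:
        amps = self.true_amplitudes()
        return amps[-1] / amps[0]

    def true_freq_adaptation(self) -> float:
        if len(self.ap_times) < 2:
            raise SpecError("frequency adaptation needs at least two APs")
        isis = np.diff(self.ap_times)
        return float(isis[-1] / isis[0])

    def ground_truth(self) -> dict:
        gt = {
            "ap_amplitude": self.true_amplitudes()[0],
            "ap_half_width": self.true_half_width,
            "ahp_amplitude": self.true_ahp_amplitude,
            "max_rise_rate": self.true_max_rise(0),
            "max_fall_rate": self.true_max_fall(0),
            "n_spikes": len(self.ap_times),
            "amp_adaptation": self.true_amp_adaptation(),
        }
        if len(self.ap_times) >= 2:
            gt["freq_adaptation"] = self.true_freq_adaptation()
        return gt


def _knots(
    spec: WaveformSpec, t_on: float, t_off: float, total_dur: float
) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoints (s, mV) of the piecewise-linear trace."""
    ms = 1e-3
    plateau = spec.pulse_plateau
    ts: list[float] = [0.0, t_on, t_on + spec.onset_ramp * ms]
    vs: list[float] = [spec.baseline, spec.baseline, plateau]
    for t0, peak in zip(spec.ap_times, spec.ap_peaks):
        # Shorten the lead ramp if the previous knot leaves too little room.
        lead_start = max(t0 - spec.lead_time * ms, ts[-1] + 0.2 * ms)
        pts = [
            (lead_start, plateau),
            (t0, spec.ap_threshold),
            (t0 + spec.rise_time * ms, peak),
            (t0 + (spec.rise_time + spec.fall_time) * ms, spec.ap_threshold),
            (
                t0 + (spec.rise_time + spec.fall_time + spec.ahp_dur / 2) * ms,
                spec.ap_threshold - spec.ahp_depth,
            ),
            (
                t0 + (spec.rise_time + spec.fall_time + spec.ahp_dur) * ms,
                plateau,
            ),
        ]
        for t, v in pts:
            if t <= ts[-1]:
                raise SpecError("AP footprints overlap after adding lead ramp")
            ts.append(t)
            vs.append(v)
    if ts[-1] < t_off:
        ts.append(t_off)
        vs.append(plateau)
    ts.append(max(t_off, ts[-1]) + spec.onset_ramp * ms)
    vs.append(spec.baseline)
    if ts[-1] < total_dur:
        ts.append(total_dur)
        vs.append(spec.baseline)
    return np.array(ts), np.array(vs)


def compose_waveform(
    spec: WaveformSpec,
    protocol: StepProtocol | None = None,
    sampling_rate: float | None = None,
    stimulus: float = 100.0,
    cell_id: str = "composed",
) -> Recording:
    """Render the spec as a full step-protocol :class:`Recording`.

    The sweep at ``stimulus`` pA carries the composed spike train; every
    other sweep is flat at baseline.  AP times must fall inside the current
    pulse.  The closed-form kinetics are stored in
    ``metadata["waveform_truth"]``.
    """
    protocol = protocol or StepProtocol()
    if sampling_rate is not None and sampling_rate != protocol.sampling_rate:
        protocol = StepProtocol(
            step_amplitudes=protocol.step_amplitudes,
            pre_stim=protocol.pre_stim,
            pulse_dur=protocol.pulse_dur,
            post_stim=protocol.post_stim,
            sampling_rate=sampling_rate,
        )
    t_on = protocol.pre_stim
    t_off = protocol.pre_stim + protocol.pulse_dur
    for t0 in spec.ap_times:
        if not (t_on <= t0 <= t_off):
            raise SpecError(
                f"AP at {t0} s lies outside the pulse window [{t_on}, {t_off}] s"
            )

    t = protocol.time()
    knot_t, knot_v = _knots(spec, t_on, t_off, protocol.total_dur)
    spiking = np.interp(t, knot_t, knot_v)
    flat = np.full(t.size, spec.baseline)

    sweeps = []
    for amp in protocol.step_amplitudes:
        samples = spiking if amp == stimulus else flat
        sweeps.append(Sweep(stimulus=float(amp), samples=samples.copy(), dt=protocol.dt))
    if stimulus not in protocol.step_amplitudes:
        sweeps.append(Sweep(stimulus=float(stimulus), samples=spiking.copy(), dt=protocol.dt))

    return Recording(
        cell_id=cell_id,
        protocol=protocol,
        sweeps=sweeps,
        series_resistance=10.0,
        metadata={"generator": "waveform", "waveform_truth": spec.ground_truth()},
    )
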