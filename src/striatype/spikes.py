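"""Action-potential detection and per-spike kinetics.

Detection follows standard patch-clamp practice: a spike onset is the first
sample at which the 3-point-smoothed derivative dV/dt reaches the criterion
(default 20 mV/ms); the peak is the voltage maximum that follows within a
short search window; a 2 ms refractory period suppresses double counting.
Per-event kinetics use the conventions documented on
:class:`~striatype.ephys.EphysFeatures`: amplitude threshold-to-peak,
half-width at the threshold/peak midpoint with linear interpolation of the
crossings, AHP threshold-to-trough within 50 ms after the peak, maximum fall
rate reported as a positive magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recording import Sweep

__all__ = ["SpikeEvent", "detect_spikes"]

DEFAULT_DVDT_CRITERION = 20.0  # mV/ms
REFRACTORY_MS = 2.0
PEAK_SEARCH_MS = 10.0
AHP_WINDOW_MS = 50.0
MIN_KINETICS_RATE_HZ = 10_000.0


@dataclass
class SpikeEvent:
    """One detected action potential with its kinetics."""

    t_threshold: float  # s
    v_threshold: float  # mV
    t_peak: float  # s
    v_peak: float  # mV
    max_rise: float  # mV/ms
    max_fall: float  # mV/ms, magnitude of the steepest repolarization
    half_width: float  # ms
    ahp_amplitude: float  # mV, threshold - trough (positive when trough below)

    @property
    def amplitude(self) -> float:
        """Threshold-to-peak amplitude (mV)."""
        return self.v_peak - self.v_threshold


def _smoothed_dvdt(v: np.ndarray, dt_ms: float) -> np.ndarray:
    """Central-difference derivative followed by a 3-point moving average."""
    dvdt = np.gradient(v) / dt_ms
    kernel = np.ones(3) / 3.0
    return np.convolve(dvdt, kernel, mode="same")


def _interp_crossing(t: np.ndarray, v: np.ndarray, i0: int, i1: int, level: float) -> float:
    """Linearly interpolated time at which v crosses ``level`` in [i0, i1]."""
    seg_v = v[i0 : i1 + 1]
    seg_t = t[i0 : i1 + 1]
    for j in range(len(seg_v) - 1):
        lo, hi = seg_v[j], seg_v[j + 1]
        if (lo < level <= hi) or (hi <= level < lo):
            frac = (level - lo) / (hi - lo)
            return float(seg_t[j] + frac * (seg_t[j + 1] - seg_t[j]))
    return float(seg_t[0])


def detect_spikes(
    sweep: Sweep, dvdt_threshold: float = DEFAULT_DVDT_CRITERION
) -> list[SpikeEvent]:
    """Detect action potentials in one sweep.

    Returns events ordered in time; an empty list when nothing crosses the
    derivative criterion.  Warns when the sampling rate is below 10 kHz,
    where the kinetics lose accuracy.
    """
    dt_ms = sweep.dt * 1000.0
    if 1.0 / sweep.dt < MIN_KINETICS_RATE_HZ:
        warnings.warn(
            f"sweep sampled at {1.0 / sweep.dt:.0f} Hz; spike kinetics need "
            ">= 10 kHz for full accuracy",
            stacklevel=2,
        )
    v = sweep.samples
    n = v.size
    if n < 5:
        return []
    t = sweep.time
    dvdt = _smoothed_dvdt(v, dt_ms)
    fast = dvdt >= dvdt_threshold
    onsets = np.nonzero(fast & ~np.roll(fast, 1))[0]
    if fast[0]:
        onsets = np.concatenate(([0], onsets[onsets != 0]))

    refractory = int(round(REFRACTORY_MS / dt_ms))
    search = max(1, int(round(PEAK_SEARCH_MS / dt_ms)))
    ahp_win = max(1, int(round(AHP_WINDOW_MS / dt_ms)))

    events: list[SpikeEvent] = []
    last_peak = -10 * refractory
    for oi, onset in enumerate(onsets):
        stop = min(n, onset + search)
        if oi + 1 < len(onsets):
            stop = min(stop, onsets[oi + 1])
        if stop <= onset:
            continue
        i_peak = onset + int(np.argmax(v[onset:stop]))
        if i_peak - last_peak < refractory:
            continue
        # Walk back from the peak to the first sub-criterion sample.
        i_thr = onset
        j = i_peak
        while j > 0 and dvdt[j - 1] >= dvdt_threshold:
            j -= 1
        i_thr = j
        v_thr = float(v[i_thr])
        v_peak = float(v[i_peak])
        if v_peak <= v_thr:
            continue
        last_peak = i_peak

        # Kinetics windows: rise = threshold..peak; fall = peak..return-to-threshold.
        i_end = i_peak
        while i_end < n - 1 and v[i_end] > v_thr and i_end - i_peak < ahp_win:
            i_end += 1
        max_rise = float(np.max(dvdt[i_thr : i_peak + 1]))
        max_fall = float(-np.min(dvdt[i_peak : i_end + 1])) if i_end > i_peak else 0.0

        mid = 0.5 * (v_thr + v_peak)
        t_up = _interp_crossing(t, v, i_thr, i_peak, mid)
        t_down = _interp_crossing(t, v, i_peak, i_end, mid) if i_end > i_peak else t[i_peak]
        half_width = max((t_down - t_up) * 1000.0, dt_ms)

        i_ahp_stop = min(n, i_peak + ahp_win)
        if oi + 1 < len(onsets):
            i_ahp_stop = min(i_ahp_stop, onsets[oi + 1])
        if i_ahp_stop > i_end:
            v_trough = float(np.min(v[i_end:i_ahp_stop]))
        else:
            v_trough = v_thr
        ahp_amplitude = v_thr - v_trough

        events.append(
            SpikeEvent(
                t_threshold=float(t[i_thr]),
                v_threshold=v_thr,
                t_peak=float(t[i_peak]),
                v_peak=v_peak,
                max_rise=max_rise,
                max_fall=max_fall,
                half_width=half_width,
                ahp_amplitude=ahp_amplitude,
            )
        )
    return events
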