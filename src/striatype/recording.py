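"""Data model for step-protocol current-clamp recordings.

A :class:`Recording` holds one cell's set of voltage sweeps, each evoked by a
rectangular current step.  The default :class:`StepProtocol` is the standard
striatal characterization protocol: one-second steps from -200 to +200 pA in
50 pA increments, with a pre- and post-stimulus baseline on either side.

Units are fixed throughout the package: membrane potential in mV, current in
pA, durations in seconds, sampling rate in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError

__all__ = ["StepProtocol", "Sweep", "Recording", "default_protocol"]

#: Default step amplitudes (pA): -200 .. +200 in 50 pA increments, 9 steps.
DEFAULT_STEP_AMPLITUDES = tuple(float(a) for a in range(-200, 201, 50))

#: Tolerance (pA) when matching a sweep's recorded command to a protocol step.
AMPLITUDE_MATCH_TOL_PA = 1.0


@dataclass(frozen=True)
class StepProtocol:
    """Rectangular current-step stimulation protocol.

    Parameters
    ----------
    step_amplitudes
        Commanded step currents in pA, ascending.
    pre_stim, pulse_dur, post_stim
        Segment durations in seconds.  The pulse is the only depolarizing /
        hyperpolarizing epoch; baselines carry zero injected current.
    sampling_rate
        Acquisition rate in Hz.
    """

    step_amplitudes: tuple[float, ...] = DEFAULT_STEP_AMPLITUDES
    pre_stim: float = 0.2
    pulse_dur: float = 1.0
    post_stim: float = 0.2
    sampling_rate: float = 20_000.0

    def __post_init__(self) -> None:
        if self.pulse_dur <= 0:
            raise ValidationError("pulse_dur must be positive")
        if self.sampling_rate < 1000:
            raise ValidationError("sampling_rate must be at least 1000 Hz")
        if self.pre_stim < 0 or self.post_stim < 0:
            raise ValidationError("baseline durations must be non-negative")
        amps = tuple(float(a) for a in self.step_amplitudes)
        if len(amps) == 0:
            raise ValidationError("protocol needs at least one step amplitude")
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValidationError("step_amplitudes must be strictly ascending")
        object.__setattr__(self, "step_amplitudes", amps)

    @property
    def total_dur(self) -> float:
        return self.pre_stim + self.pulse_dur + self.post_stim

    @property
    def n_samples(self) -> int:
        return int(round(self.total_dur * self.sampling_rate))

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.sampling_rate

    def time(self) -> np.ndarray:
        """Time axis in seconds from sweep start."""
        return np.arange(self.n_samples) * self.dt

    def pulse_window(self) -> tuple[int, int]:
        """(start, stop) sample indices of the current pulse."""
        i0 = int(round(self.pre_stim * self.sampling_rate))
        i1 = int(round((self.pre_stim + self.pulse_dur) * self.sampling_rate))
        return i0, i1


@dataclass
class Sweep:
    """One voltage trace evoked by one current step."""

    stimulus: float  # pA
    samples: np.ndarray  # mV
    dt: float  # s

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("sweep samples must be a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("sweep samples must all be finite")
        if self.dt <= 0:
            raise ValidationError("sweep dt must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt


@dataclass
class Recording:
    """One cell's complete step-protocol recording plus QC metadata."""

    cell_id: str
    protocol: StepProtocol
    sweeps: list[Sweep]
    series_resistance: float | None = None  # MOhm, from the amplifier
    source_path: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = sorted(self.sweeps, key=lambda s: s.stimulus)
        n_expected = self.protocol.n_samples
        for sw in self.sweeps:
            if abs(sw.samples.size - n_expected) > 1:
                raise ValidationError(
                    f"sweep at {sw.stimulus} pA has {sw.samples.size} samples, "
                    f"protocol implies {n_expected}"
                )

    def sweep_at(self, amplitude: float, tol: float = AMPLITUDE_MATCH_TOL_PA) -> Sweep:
        """Return the sweep whose stimulus is nearest ``amplitude``.

        Raises :class:`ValidationError` if the nearest sweep is farther than
        ``tol`` pA from the requested amplitude.
        """
        if not self.sweeps:
            raise ValidationError("recording has no sweeps")
        best = min(self.sweeps, key=lambda s: abs(s.stimulus - amplitude))
        if abs(best.stimulus - amplitude) > tol:
            raise ValidationError(
                f"no sweep within {tol} pA of {amplitude} pA "
                f"(nearest: {best.stimulus} pA)"
            )
        return best

    @property
    def stimuli(self) -> list[float]:
        return [s.stimulus for s in self.sweeps]

    def baseline_window(self) -> tuple[int, int]:
        """Sample window of the pre-stimulus baseline."""
        return 0, int(round(self.protocol.pre_stim * self.protocol.sampling_rate))

    def with_cell_id(self, cell_id: str) -> "Recording":
        return replace(self, cell_id=cell_id)


def default_protocol(sampling_rate: float = 20_000.0) -> StepProtocol:
    """The standard striatal step protocol at the given sampling rate."""
    return StepProtocol(sampling_rate=sampling_rate)
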