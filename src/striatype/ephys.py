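"""The 12 intrinsic electrical properties.

Extracted per cell from a QC-passed step-protocol recording:

==================  =====  =====================================================
feature             units  definition (package default, overridable)
==================  =====  =====================================================
capacitance         pF     tau / R_in, tau from an exponential fit to the
                           -50 pA step onset (first 300 ms)
input_resistance    MOhm   least-squares slope of steady-state delta-V vs
                           injected current over all non-spiking steps
rmp                 mV     mean pre-stimulus baseline across sweeps
sag                 mV     steady-state V minus minimum V on the -200 pA step
rheobase            pA     smallest step amplitude evoking >= 1 spike
ap_amplitude        mV     threshold-to-peak, first spike of the rheobase sweep
ahp_amplitude       mV     threshold-to-trough within 50 ms post-peak
ap_half_width       ms     width at the threshold/peak midpoint
max_rise_rate       mV/ms  maximum smoothed dV/dt on the rising flank
max_fall_rate       mV/ms  magnitude of the steepest repolarization slope
freq_adaptation     ratio  ISI_last / ISI_first on the smallest step with
                           >= 10 spikes
amp_adaptation      ratio  amplitude_last / amplitude_first on that same step
==================  =====  =====================================================

Features that cannot be measured (no spikes anywhere, no 10-spike train) are
NaN with an explicit flag, never silently dropped.  Steady-state windows are
the last 100 ms of the pulse; the baseline window is the full pre-stimulus
segment; times are seconds from sweep start with 0-based sample indexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import ExtractionError
from .qc import apply_qc
from .recording import Recording, Sweep
from .spikes import DEFAULT_DVDT_CRITERION, SpikeEvent, detect_spikes

__all__ = [
    "FEATURE_NAMES",
    "EphysFeatures",
    "compute_rmp",
    "compute_input_resistance",
    "compute_capacitance",
    "compute_sag",
    "compute_rheobase",
    "ap_waveform_features",
    "adaptation_features",
    "extract_features",
    "features_table",
]

#: Canonical order of the 12 intrinsic electrical properties.
FEATURE_NAMES = (
    "capacitance",
    "input_resistance",
    "rmp",
    "sag",
    "rheobase",
    "ap_amplitude",
    "ahp_amplitude",
    "ap_half_width",
    "max_rise_rate",
    "max_fall_rate",
    "freq_adaptation",
    "amp_adaptation",
)

STEADY_STATE_MS = 100.0  # window at the end of the pulse
CAP_FIT_MS = 300.0  # onset window for the exponential fit
CAP_FIT_STEP_PA = -50.0
SAG_STEP_PA = -200.0
MIN_SPIKES_FOR_ADAPTATION = 10


@dataclass
class EphysFeatures:
    """The 12-element intrinsic-property vector for one cell."""

    cell_id: str
    capacitance: float = float("nan")
    input_resistance: float = float("nan")
    rmp: float = float("nan")
    sag: float = float("nan")
    rheobase: float = float("nan")
    ap_amplitude: float = float("nan")
    ahp_amplitude: float = float("nan")
    ap_half_width: float = float("nan")
    max_rise_rate: float = float("nan")
    max_fall_rate: float = float("nan")
    freq_adaptation: float = float("nan")
    amp_adaptation: float = float("nan")
    adaptation_defined: bool = True
    rheobase_defined: bool = True
    tau_m: float = float("nan")  # by-product of the capacitance fit (ms)
    notes: dict = field(default_factory=dict)

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_series(self) -> pd.Series:
        s = pd.Series({name: getattr(self, name) for name in FEATURE_NAMES})
        s["adaptation_defined"] = self.adaptation_defined
        s["rheobase_defined"] = self.rheobase_defined
        s.name = self.cell_id
        return s


def _steady_window(rec: Recording) -> tuple[int, int]:
    i0, i1 = rec.protocol.pulse_window()
    w = int(round(STEADY_STATE_MS / 1000.0 * rec.protocol.sampling_rate))
    return max(i0, i1 - w), i1


def _baseline(rec: Recording, sweep: Sweep) -> float:
    b0, b1 = rec.baseline_window()
    return float(np.mean(sweep.samples[b0:b1]))


def compute_rmp(rec: Recording) -> float:
    """Resting membrane potential: mean pre-stimulus baseline over sweeps (mV)."""
    if rec.protocol.pre_stim < 0.1:
        raise ExtractionError("RMP needs >= 100 ms of pre-stimulus baseline")
    return float(np.mean([_baseline(rec, sw) for sw in rec.sweeps]))


def _spikes_per_sweep(
    rec: Recording, dvdt_threshold: float = DEFAULT_DVDT_CRITERION
) -> dict[float, list[SpikeEvent]]:
    return {sw.stimulus: detect_spikes(sw, dvdt_threshold) for sw in rec.sweeps}


def compute_input_resistance(
    rec: Recording, spikes: dict[float, list[SpikeEvent]] | None = None
) -> float:
    """Input resistance (MOhm): slope of steady-state delta-V versus current.

    Uses every non-spiking step; delta-V is the mean of the last 100 ms of the
    pulse minus that sweep's own baseline.  mV/pA converts to MOhm x 1000.
    """
    spikes = spikes if spikes is not None else _spikes_per_sweep(rec)
    s0, s1 = _steady_window(rec)
    currents, dvs = [], []
    for sw in rec.sweeps:
        if spikes.get(sw.stimulus):
            continue
        currents.append(sw.stimulus)
        dvs.append(float(np.mean(sw.samples[s0:s1])) - _baseline(rec, sw))
    if len(currents) < 2:
        raise ExtractionError("input resistance needs >= 2 non-spiking steps")
    slope = np.polyfit(currents, dvs, 1)[0]  # mV/pA = GOhm
    return float(slope * 1000.0)


def compute_capacitance(
    rec: Recording, input_resistance: float | None = None
) -> tuple[float, float]:
    """Membrane capacitance (pF) and time constant tau (ms).

    Fits V(t) = V0 + dV (1 - exp(-t/tau)) to the onset (first 300 ms) of the
    -50 pA step (falling back to the nearest hyperpolarizing step) and
    converts via C = tau / R_in.
    """
    if input_resistance is None:
        input_resistance = compute_input_resistance(rec)
    if input_resistance <= 0:
        raise ExtractionError("capacitance needs a positive input resistance")
    hyper = [sw for sw in rec.sweeps if sw.stimulus < 0]
    if not hyper:
        raise ExtractionError("capacitance needs a hyperpolarizing step")
    sw = min(hyper, key=lambda s: abs(s.stimulus - CAP_FIT_STEP_PA))
    i0, _ = rec.protocol.pulse_window()
    n_fit = int(round(CAP_FIT_MS / 1000.0 * rec.protocol.sampling_rate))
    seg = sw.samples[i0 : i0 + n_fit]
    t_ms = np.arange(seg.size) / rec.protocol.sampling_rate * 1000.0

    v0 = _baseline(rec, sw)
    dv0 = float(seg[-1]) - v0
    model = lambda t, dv, tau: v0 + dv * (1.0 - np.exp(-t / tau))
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            (dv, tau), _ = curve_fit(
                model, t_ms, seg,
                p0=[dv0 if dv0 != 0 else -1.0, max(t_ms[-1] / 5, 1.0)],
                maxfev=10_000,
            )
    except RuntimeError as exc:
        raise ExtractionError(f"exponential fit did not converge: {exc}") from exc
    if tau <= 0 or tau < 2.0 * 1000.0 / rec.protocol.sampling_rate:
        raise ExtractionError(
            f"fitted tau {tau:.4f} ms at or below temporal resolution; "
            "onset is not exponential"
        )
    capacitance = tau / input_resistance * 1000.0  # ms/MOhm -> pF
    return float(capacitance), float(tau)


def compute_sag(rec: Recording) -> float:
    """Voltage sag (mV) on the -200 pA step: steady-state V minus minimum V.

    Falls back to the most hyperpolarizing available step with a warning note;
    clipped at zero for monotone responses.
    """
    hyper = [sw for sw in rec.sweeps if sw.stimulus < 0]
    if not hyper:
        raise ExtractionError("sag needs a hyperpolarizing step")
    matches = [sw for sw in hyper if abs(sw.stimulus - SAG_STEP_PA) <= 1.0]
    if matches:
        sw = matches[0]
    else:
        import warnings

        sw = min(hyper, key=lambda s: s.stimulus)
        warnings.warn(
            f"no -200 pA sweep; computing sag on {sw.stimulus} pA", stacklevel=2
        )
    i0, i1 = rec.protocol.pulse_window()
    s0, s1 = _steady_window(rec)
    v_steady = float(np.mean(sw.samples[s0:s1]))
    v_min = float(np.min(sw.samples[i0:i1]))
    return max(v_steady - v_min, 0.0)


def compute_rheobase(
    rec: Recording, spikes: dict[float, list[SpikeEvent]] | None = None
) -> float:
    """Rheobase (pA): smallest step whose sweep contains >= 1 spike; NaN if none."""
    spikes = spikes if spikes is not None else _spikes_per_sweep(rec)
    for sw in rec.sweeps:  # sweeps sorted ascending
        if spikes.get(sw.stimulus):
            return float(sw.stimulus)
    return float("nan")


def ap_waveform_features(
    rec: Recording, spikes: dict[float, list[SpikeEvent]] | None = None
) -> dict[str, float]:
    """AP kinetics from the first spike of the rheobase sweep.

    Returns NaN for all five quantities when rheobase is undefined.
    """
    spikes = spikes if spikes is not None else _spikes_per_sweep(rec)
    rheo = compute_rheobase(rec, spikes)
    keys = ("ap_amplitude", "ahp_amplitude", "ap_half_width", "max_rise_rate", "max_fall_rate")
    if np.isnan(rheo):
        return {k: float("nan") for k in keys}
    ev = spikes[rheo][0]
    return {
        "ap_amplitude": ev.amplitude,
        "ahp_amplitude": ev.ahp_amplitude,
        "ap_half_width": ev.half_width,
        "max_rise_rate": ev.max_rise,
        "max_fall_rate": ev.max_fall,
    }


def adaptation_features(
    rec: Recording, spikes: dict[float, list[SpikeEvent]] | None = None
) -> tuple[float, float, bool]:
    """Frequency and amplitude adaptation ratios.

    Measured on the smallest step that elicited at least 10 action
    potentials: ISI_last/ISI_first and amplitude_last/amplitude_first.
    Returns (NaN, NaN, False) when no step reaches 10 spikes.
    """
    spikes = spikes if spikes is not None else _spikes_per_sweep(rec)
    for sw in rec.sweeps:
        evs = spikes.get(sw.stimulus, [])
        if len(evs) >= MIN_SPIKES_FOR_ADAPTATION:
            times = np.array([e.t_peak for e in evs])
            isis = np.diff(times)
            freq_ad = float(isis[-1] / isis[0])
            amp_ad = float(evs[-1].amplitude / evs[0].amplitude)
            return freq_ad, amp_ad, True
    return float("nan"), float("nan"), False


def extract_features(
    rec: Recording,
    dvdt_threshold: float = DEFAULT_DVDT_CRITERION,
    require_qc: bool = False,
) -> EphysFeatures:
    """Assemble the full 12-property vector for one recording.

    Deterministic for a fixed recording.  Per-feature failures are recorded
    in ``notes`` with the feature set to NaN; nothing is silently dropped.
    With ``require_qc`` the recording must pass the default exclusion rules.
    """
    if require_qc:
        report = apply_qc(rec)
        if not report.passed:
            raise ExtractionError(
                f"{rec.cell_id} failed QC: {'; '.join(report.reasons)}"
            )
    spikes = _spikes_per_sweep(rec, dvdt_threshold)
    feats = EphysFeatures(cell_id=rec.cell_id)

    def attempt(name, fn):
        try:
            return fn()
        except ExtractionError as exc:
            feats.notes[name] = str(exc)
            return None

    rmp = attempt("rmp", lambda: compute_rmp(rec))
    if rmp is not None:
        feats.rmp = rmp
    rin = attempt("input_resistance", lambda: compute_input_resistance(rec, spikes))
    if rin is not None:
        feats.input_resistance = rin
        cap = attempt("capacitance", lambda: compute_capacitance(rec, rin))
        if cap is not None:
            feats.capacitance, feats.tau_m = cap
    sag = attempt("sag", lambda: compute_sag(rec))
    if sag is not None:
        feats.sag = sag

    rheo = compute_rheobase(rec, spikes)
    feats.rheobase = rheo
    feats.rheobase_defined = not np.isnan(rheo)
    for k, v in ap_waveform_features(rec, spikes).items():
        setattr(feats, k, v)
    feats.freq_adaptation, feats.amp_adaptation, feats.adaptation_defined = (
        adaptation_features(rec, spikes)
    )
    return feats


def features_table(features: list[EphysFeatures]) -> pd.DataFrame:
    """One row per cell, the 12 feature columns plus definition flags."""
    df = pd.DataFrame([f.as_series() for f in features])
    df.index.name = "cell_id"
    return df
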