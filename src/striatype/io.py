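"""Readers and writers for recordings.

Three surfaces:

* the internal container — a single JSON file holding the protocol header and
  the per-sweep sample arrays (schema below).  Lossless round-trip, no binary
  dependencies, used by the whole test suite;
* Axon Binary Format (.abf), through the optional ``pyabf`` backend;
* Neurodata Without Borders export, through the optional ``pynwb`` backend.

Internal JSON schema (version 1)::

    {
      "format": "striatype-recording",
      "version": 1,
      "cell_id": str,
      "series_resistance": float | null,     # MOhm
      "source_path": str,
      "metadata": {...},
      "protocol": {
        "step_amplitudes": [pA, ...],
        "pre_stim": s, "pulse_dur": s, "post_stim": s,
        "sampling_rate": Hz
      },
      "sweeps": [{"stimulus": pA, "samples": [mV, ...]}, ...]
    }

Floats are serialized with full ``repr`` precision, so write -> read is the
identity on every stored value.
"""

from __future__ import annotations

import json
import os
import warnings

import numpy as np

from .exceptions import FormatError, MissingDependencyError, ValidationError
from .recording import AMPLITUDE_MATCH_TOL_PA, Recording, StepProtocol, Sweep

__all__ = ["read_internal", "write_internal", "read_abf", "export_nwb"]

_FORMAT_TAG = "striatype-recording"

_PROTOCOL_FIELDS = ("step_amplitudes", "pre_stim", "pulse_dur", "post_stim", "sampling_rate")


def write_internal(rec: Recording, path: str | os.PathLike) -> None:
    """Serialize a :class:`Recording` to the internal JSON container."""
    doc = {
        "format": _FORMAT_TAG,
        "version": 1,
        "cell_id": rec.cell_id,
        "series_resistance": rec.series_resistance,
        "source_path": rec.source_path,
        "metadata": rec.metadata,
        "protocol": {
            "step_amplitudes": list(rec.protocol.step_amplitudes),
            "pre_stim": rec.protocol.pre_stim,
            "pulse_dur": rec.protocol.pulse_dur,
            "post_stim": rec.protocol.post_stim,
            "sampling_rate": rec.protocol.sampling_rate,
        },
        "sweeps": [
            {"stimulus": sw.stimulus, "samples": sw.samples.tolist()} for sw in rec.sweeps
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_internal(path: str | os.PathLike) -> Recording:
    """Read a recording from the internal JSON container.

    Raises :class:`ValidationError` naming the offending field on schema
    violations, :class:`FormatError` if the file is not this container at all.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT_TAG:
        raise FormatError(f"{path}: missing '{_FORMAT_TAG}' format tag")
    proto_doc = doc.get("protocol")
    if not isinstance(proto_doc, dict):
        raise ValidationError(f"{path}: missing or invalid field 'protocol'")
    for key in _PROTOCOL_FIELDS:
        if key not in proto_doc:
            raise ValidationError(f"{path}: protocol missing field '{key}'")
    protocol = StepProtocol(
        step_amplitudes=tuple(proto_doc["step_amplitudes"]),
        pre_stim=float(proto_doc["pre_stim"]),
        pulse_dur=float(proto_doc["pulse_dur"]),
        post_stim=float(proto_doc["post_stim"]),
        sampling_rate=float(proto_doc["sampling_rate"]),
    )
    sweeps_doc = doc.get("sweeps")
    if not isinstance(sweeps_doc, list):
        raise ValidationError(f"{path}: missing or invalid field 'sweeps'")
    sweeps = []
    for i, sd in enumerate(sweeps_doc):
        if "stimulus" not in sd or "samples" not in sd:
            raise ValidationError(f"{path}: sweep {i} missing 'stimulus' or 'samples'")
        sweeps.append(
            Sweep(
                stimulus=float(sd["stimulus"]),
                samples=np.asarray(sd["samples"], dtype=float),
                dt=protocol.dt,
            )
        )
    rs = doc.get("series_resistance")
    return Recording(
        cell_id=str(doc.get("cell_id", "")),
        protocol=protocol,
        sweeps=sweeps,
        series_resistance=None if rs is None else float(rs),
        source_path=str(doc.get("source_path", "")),
        metadata=doc.get("metadata", {}),
    )


def read_abf(
    path: str | os.PathLike,
    protocol: StepProtocol | None = None,
) -> Recording:
    """Read an Axon Binary Format current-clamp file into a :class:`Recording`.

    Sweeps are matched to protocol steps by the recorded command amplitude
    (nearest neighbor, 1 pA tolerance); a mismatch between sweep count and
    protocol steps produces a warning and a best-effort mapping.  Requires
    the optional ``pyabf`` dependency.
    """
    try:
        import pyabf
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise MissingDependencyError(
            "reading .abf files requires the optional 'pyabf' package "
            "(pip install striatype[abf])"
        ) from exc

    try:
        abf = pyabf.ABF(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable ABF file ({exc})") from exc

    if "clamp" in str(getattr(abf, "adcUnits", [""])[0]).lower() or str(
        abf.adcUnits[0]
    ).lower().startswith(("pa", "na")):
        raise FormatError(f"{path}: voltage-clamp file, expected current clamp")

    scale_v = 1.0 if "mv" in str(abf.adcUnits[0]).lower() else 1000.0

    sweeps = []
    commands = []
    for i in abf.sweepList:
        abf.sweepSetX = None  # noqa: keep pyabf happy across versions
        abf.setSweep(i)
        samples = np.asarray(abf.sweepY, dtype=float) * scale_v
        cmd = np.asarray(abf.sweepC, dtype=float)
        # Command amplitude: largest-|deviation| epoch value relative to holding.
        holding = cmd[0]
        dev = cmd - holding
        amp = float(dev[np.argmax(np.abs(dev))])
        commands.append(amp)
        sweeps.append((amp, samples))

    fs = float(abf.dataRate)
    if protocol is None:
        # Infer segment durations from the first sweep's command trace.
        abf.setSweep(0)
        cmd = np.asarray(abf.sweepC, dtype=float)
        dev = np.abs(cmd - cmd[0]) > 1e-9
        if dev.any():
            on = int(np.argmax(dev))
            off = int(len(dev) - np.argmax(dev[::-1]))
        else:
            on, off = 0, len(cmd)
        amps = sorted(set(round(c, 1) for c in commands))
        protocol = StepProtocol(
            step_amplitudes=tuple(amps) if len(amps) > 1 else (amps[0],),
            pre_stim=on / fs,
            pulse_dur=(off - on) / fs,
            post_stim=(len(cmd) - off) / fs,
            sampling_rate=fs,
        )

    if len(sweeps) != len(protocol.step_amplitudes):
        warnings.warn(
            f"{path}: {len(sweeps)} sweeps but protocol defines "
            f"{len(protocol.step_amplitudes)} steps; mapping by command amplitude",
            stacklevel=2,
        )

    mapped = []
    for amp, samples in sweeps:
        matches = [
            a for a in protocol.step_amplitudes if abs(a - amp) <= AMPLITUDE_MATCH_TOL_PA
        ]
        stim = matches[0] if matches else amp
        mapped.append(Sweep(stimulus=stim, samples=samples, dt=1.0 / fs))

    return Recording(
        cell_id=os.path.splitext(os.path.basename(str(path)))[0],
        protocol=protocol,
        sweeps=mapped,
        source_path=str(path),
    )


def export_nwb(rec: Recording, path: str | os.PathLike) -> None:
    """Export a recording to a Neurodata Without Borders file.

    Requires the optional ``pynwb`` dependency; each sweep becomes one
    CurrentClampSeries with its stimulus description.
    """
    try:
        from datetime import datetime, timezone

        from pynwb import NWBHDF5IO, NWBFile
        from pynwb.icephys import CurrentClampSeries
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise MissingDependencyError(
            "NWB export requires the optional 'pynwb' package "
            "(pip install striatype[nwb])"
        ) from exc

    nwbfile = NWBFile(
        session_description="current-clamp step protocol",
        identifier=rec.cell_id,
        session_start_time=datetime.now(timezone.utc),
    )
    device = nwbfile.create_device(name="amplifier")
    electrode = nwbfile.create_icephys_electrode(
        name="electrode0", device=device, description="patch electrode"
    )
    for i, sw in enumerate(rec.sweeps):
        series = CurrentClampSeries(
            name=f"sweep{i:03d}",
            data=sw.samples * 1e-3,  # volts
            electrode=electrode,
            rate=rec.protocol.sampling_rate,
            gain=1.0,
            stimulus_description=f"{sw.stimulus} pA step",
            conversion=1.0,
        )
        nwbfile.add_acquisition(series)
    with NWBHDF5IO(str(path), "w") as io_:
        io_.write(nwbfile)
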