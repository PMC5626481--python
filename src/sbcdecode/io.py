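"""Readers and writers: WAV waveforms and HDF5 event containers.

WAV headers store integer sample rates, but the nominal audio rate here
(97656.25 Hz) is fractional; the exact rate therefore travels in a JSON
sidecar (``<name>.wav.json``) which takes precedence over the header on
read.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .spiketrains import EventTrainSet, UnitTrains
from .stimulus import Waveform

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Unreadable or unsupported file content."""


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_waveform(wave: Waveform, path, meta: dict = None) -> None:
    """Write a mono float32 WAV plus a JSON sidecar with the exact rate."""
    path = Path(path)
    wavfile.write(path, int(round(wave.sample_rate)), wave.samples.astype(np.float32))
    side = {"sample_rate": wave.sample_rate}
    if meta:
        side.update(meta)
    _sidecar(path).write_text(json.dumps(side))


def read_waveform(path) -> Waveform:
    """Read a mono WAV; a sidecar sample rate overrides the header."""
    path = Path(path)
    try:
        header_rate, data = wavfile.read(path)
    except Exception as err:
        raise FormatError(f"cannot read WAV file {path}: {err}") from err
    if data.ndim != 1:
        raise FormatError(f"{path}: expected mono audio, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    rate = float(header_rate)
    side = _sidecar(path)
    if side.exists():
        rate = float(json.loads(side.read_text())["sample_rate"])
    return Waveform(np.asarray(data, dtype=float), rate)


def write_events(events: EventTrainSet, path, meta: dict = None) -> None:
    """Write an event-train container:
    ``/units/<i>/cf``, ``/units/<i>/trials/<j>/times`` (s, sorted) and
    ``.../success`` (bool), with ``schema_version`` and ``duration``
    attributes at the root."""
    path = Path(path)
    with h5py.File(path, "w") as h:
        h.attrs["schema_version"] = SCHEMA_VERSION
        h.attrs["duration"] = events.duration
        if meta:
            for k, v in meta.items():
                h.attrs[k] = v
        grp = h.create_group("units")
        for i, unit in enumerate(events.units):
            ug = grp.create_group(f"{i:04d}")
            ug.attrs["cf"] = unit.cf
            tg = ug.create_group("trials")
            for j in range(unit.n_trials):
                jg = tg.create_group(f"{j:04d}")
                jg.create_dataset("times", data=unit.times[j])
                jg.create_dataset("success", data=unit.success[j])


def read_events(path) -> EventTrainSet:
    """Read and validate an event-train container written by
    :func:`write_events`; validation errors name the offending
    unit/trial."""
    path = Path(path)
    with h5py.File(path, "r") as h:
        if "schema_version" not in h.attrs:
            raise FormatError(f"{path}: missing schema_version attribute")
        if int(h.attrs["schema_version"]) != SCHEMA_VERSION:
            raise FormatError(
                f"{path}: unsupported schema version {h.attrs['schema_version']}"
            )
        duration = float(h.attrs["duration"])
        units = []
        for i, uname in enumerate(sorted(h["units"])):
            ug = h["units"][uname]
            if "cf" not in ug.attrs:
                raise FormatError(f"{path}: unit {i} missing cf")
            times, success = [], []
            for j, jname in enumerate(sorted(ug["trials"])):
                jg = ug["trials"][jname]
                if "times" not in jg or "success" not in jg:
                    raise FormatError(f"{path}: unit {i} trial {j} missing fields")
                t = jg["times"][...]
                s = jg["success"][...]
                if s.dtype != bool:
                    raise FormatError(
                        f"{path}: unit {i} trial {j}: success labels must be boolean"
                    )
                if t.size > 1 and not np.all(np.diff(t) > 0):
                    raise FormatError(
                        f"{path}: unit {i} trial {j}: times not strictly increasing"
                    )
                times.append(t)
                success.append(s)
            units.append(UnitTrains(cf=float(ug.attrs["cf"]), times=times,
                                    success=success))
    return EventTrainSet(units, duration)
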