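"""Event-train containers and binning.

The recordings this package models are juxtacellular recordings at the
endbulb of Held synapse: every presynaptic event (EPSP) is observed and
labelled by whether it triggered a postsynaptic action potential.  The
union of both event classes is the auditory-nerve-fiber (ANF) input, the
successes alone are the spherical-bushy-cell (SBC) output, and the
failures form their own stream (``epsp_fail``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Event-stream selectors: which label class enters an analysis.
STREAMS = ("anf", "sbc", "epsp_fail")


@dataclass
class UnitTrains:
    """Multi-trial event trains of one unit.

    Parameters
    ----------
    cf : float
        Characteristic frequency in Hz.
    times : list of ndarray
        Per-trial event times in seconds, strictly increasing.
    success : list of ndarray of bool
        Parallel to ``times``; True marks an EPSP that triggered a
        postsynaptic spike (SBC output event), False a failure.
    """

    cf: float
    times: list = field(default_factory=list)
    success: list = field(default_factory=list)

    def __post_init__(self):
        self.times = [np.asarray(t, dtype=float) for t in self.times]
        self.success = [np.asarray(s, dtype=bool) for s in self.success]
        if len(self.times) != len(self.success):
            raise ValueError("times and success must have one entry per trial")
        for j, (t, s) in enumerate(zip(self.times, self.success)):
            if t.shape != s.shape:
                raise ValueError(f"trial {j}: times/labels length mismatch")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"trial {j}: event times not strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.times)

    def copy(self) -> "UnitTrains":
        return UnitTrains(
            cf=self.cf,
            times=[t.copy() for t in self.times],
            success=[s.copy() for s in self.success],
        )

    def stream_times(self, trial: int, stream: str) -> np.ndarray:
        """Event times of one trial restricted to a stream."""
        mask = _stream_mask(self.success[trial], stream)
        return self.times[trial][mask]


@dataclass
class EventTrainSet:
    """A population of :class:`UnitTrains` sharing one recording window."""

    units: list
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for i, u in enumerate(self.units):
            for j, t in enumerate(u.times):
                if t.size and (t[0] < 0 or t[-1] > self.duration):
                    raise ValueError(
                        f"unit {i} trial {j}: event times outside [0, duration]"
                    )

    @property
    def n_units(self) -> int:
        return len(self.units)

    def copy(self) -> "EventTrainSet":
        return EventTrainSet([u.copy() for u in self.units], self.duration)


@dataclass
class BinnedResponse:
    """Population response binned at a fixed frame rate.

    ``counts`` holds trial-summed event counts, units x time bins; the
    frame rate defaults to the 2 kHz time base shared with the stimulus
    spectrogram.  ``rate`` converts to a trial-averaged rate in Hz.
    """

    counts: np.ndarray
    frame_rate: float
    stream: str
    n_trials: int = 1

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (units x bins)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def rate(self) -> np.ndarray:
        """Trial-averaged instantaneous rate, units x bins, in Hz."""
        return self.counts * (self.frame_rate / self.n_trials)

    def slice_time(self, start: float, stop: float) -> "BinnedResponse":
        b0 = int(round(start * self.frame_rate))
        b1 = int(round(stop * self.frame_rate))
        return BinnedResponse(
            self.counts[:, b0:b1], self.frame_rate, self.stream, self.n_trials
        )


def _stream_mask(success: np.ndarray, stream: str) -> np.ndarray:
    if stream == "anf":
        return np.ones_like(success, dtype=bool)
    if stream == "sbc":
        return success
    if stream == "epsp_fail":
        return ~success
    raise ValueError(f"unknown stream {stream!r}; expected one of {STREAMS}")


def n_bins_for(duration: float, frame_rate: float) -> int:
    # floor with a guard against float slop just below an integer
    return int(np.floor(duration * frame_rate + 1e-9))


def _bin_indices(times: np.ndarray, frame_rate: float, n_bins: int) -> np.ndarray:
    """Half-open binning [b/fr, (b+1)/fr); the event at t == duration is
    folded into the last bin so totals are conserved."""
    idx = np.floor(times * frame_rate).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def bin_events(
    events: EventTrainSet, stream: str = "anf", frame_rate: float = 2000.0
) -> BinnedResponse:
    """Bin a population of event trains into a units x bins count matrix.

    Counts are summed across trials; bins are half-open intervals
    ``[b/frame_rate, (b+1)/frame_rate)``.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    nb = n_bins_for(events.duration, frame_rate)
    counts = np.zeros((events.n_units, nb), dtype=np.int64)
    n_trials = max((u.n_trials for u in events.units), default=1)
    for i, unit in enumerate(events.units):
        for j in range(unit.n_trials):
            t = unit.stream_times(j, stream)
            if t.size:
                np.add.at(counts[i], _bin_indices(t, frame_rate, nb), 1)
    return BinnedResponse(counts, frame_rate, stream, n_trials)


def bin_unit_trials(
    unit: UnitTrains, duration: float, stream: str = "anf", frame_rate: float = 2000.0
) -> np.ndarray:
    """Per-trial binned counts of one unit: trials x bins matrix."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    nb = n_bins_for(duration, frame_rate)
    out = np.zeros((unit.n_trials, nb), dtype=np.int64)
    for j in range(unit.n_trials):
        t = unit.stream_times(j, stream)
        if t.size:
            np.add.at(out[j], _bin_indices(t, frame_rate, nb), 1)
    return out
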