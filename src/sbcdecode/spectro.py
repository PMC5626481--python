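"""Short-term Fourier spectrograms on the shared 2 kHz time base.

The analysis time base is deliberately oversampled relative to the STFT
window: frames of ``window_samples`` audio samples start at
``round(i * source_rate / frame_rate)``, so neighbouring frames overlap
by many samples and the spectrogram shares its frame rate with the
binned neural response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .stimulus import Waveform


@dataclass
class Spectrogram:
    """Time x frequency power matrix in dB (10*log10)."""

    values: np.ndarray  # (n_frames, n_freqs), dB
    freq_axis: np.ndarray  # Hz, strictly increasing
    frame_rate: float
    window_samples: int
    source_rate: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x frequency)")
        if self.values.shape[1] != self.freq_axis.size:
            raise ValueError("freq_axis must have one entry per column")
        if self.freq_axis.size > 1 and not np.all(np.diff(self.freq_axis) > 0):
            raise ValueError("freq_axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrogram values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_freqs(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def slice_time(self, start: float, stop: float) -> "Spectrogram":
        b0 = int(round(start * self.frame_rate))
        b1 = int(round(stop * self.frame_rate))
        return Spectrogram(
            self.values[b0:b1], self.freq_axis, self.frame_rate,
            self.window_samples, self.source_rate,
        )


def n_frames_for(n_samples: int, window_samples: int, frame_rate: float,
                 source_rate: float) -> int:
    if n_samples < window_samples:
        raise ValueError("waveform shorter than one analysis window")
    return int(np.floor((n_samples - window_samples) * frame_rate / source_rate)) + 1


def compute_spectrogram(
    wave: Waveform,
    frame_rate: float = 2000.0,
    window_samples: int = 512,
    window: str = "hann",
    db_floor: float = 60.0,
) -> Spectrogram:
    """STFT power spectrogram with frames anchored to the analysis rate.

    Frame ``i`` starts at audio sample ``round(i * source_rate /
    frame_rate)`` and spans ``window_samples`` samples.  Power is
    ``|FFT|**2`` of the windowed frame in dB, clipped ``db_floor`` dB
    below the maximum so silence stays finite.
    """
    x = wave.samples
    n = x.size
    nf = n_frames_for(n, window_samples, frame_rate, wave.sample_rate)
    starts = np.round(np.arange(nf) * wave.sample_rate / frame_rate).astype(np.intp)
    win = get_window(window, window_samples, fftbins=True)
    frames = x[starts[:, None] + np.arange(window_samples)] * win
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    freq = np.fft.rfftfreq(window_samples, 1.0 / wave.sample_rate)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(power)
    top = db.max() if np.isfinite(db).any() else 0.0
    db = np.clip(db, top - db_floor, None)
    return Spectrogram(db, freq, frame_rate, window_samples, wave.sample_rate)


def restrict_band(spec: Spectrogram, low: float, high: float) -> Spectrogram:
    """Keep frequency columns with ``low <= f <= high``."""
    if low >= high:
        raise ValueError("low must be below high")
    mask = (spec.freq_axis >= low) & (spec.freq_axis <= high)
    if not mask.any():
        raise ValueError(
            f"band [{low}, {high}] Hz selects no columns of the frequency axis"
        )
    return Spectrogram(
        spec.values[:, mask], spec.freq_axis[mask], spec.frame_rate,
        spec.window_samples, spec.source_rate,
    )


def band_envelope(spec: Spectrogram, cf: float, bandwidth_octaves: float) -> np.ndarray:
    """Amplitude envelope near ``cf``: sqrt of Gaussian-in-log-frequency
    weighted linear power, one value per frame."""
    f = spec.freq_axis
    pos = f > 0
    w = np.zeros_like(f)
    w[pos] = np.exp(-0.5 * (np.log2(f[pos] / cf) / bandwidth_octaves) ** 2)
    if w.sum() == 0:
        raise ValueError("cf outside the spectrogram frequency axis support")
    w /= w.sum()
    power = 10.0 ** (spec.values / 10.0)
    return np.sqrt(power @ w)
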