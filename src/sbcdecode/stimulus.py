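"""Synthesis of segmented, amplitude-modulated noise stimuli.

The acoustic stimulus emulated here is a chain of environmental-sound
textures: band-limited noise carriers multiplied by slow random
envelopes, joined by cos^2/sin^2 amplitude crossfades so no transient
occurs at segment boundaries.  Segment parameters span the contrast
between weakly modulated broadband textures (rain-like) and
nearly-fully modulated ones (sand-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

#: Nominal audio sampling rate in Hz.
DEFAULT_SAMPLE_RATE = 97656.25


@dataclass(frozen=True)
class SegmentSpec:
    """One stimulus segment: a modulated band-limited noise texture.

    duration
        Segment length in seconds (inclusive of shared crossfade halves,
        see :func:`synthesize_stimulus`).
    band_low, band_high
        Carrier noise band edges in Hz.
    modulation_depth
        0 = unmodulated, 1 = envelope reaches down to zero.
    modulation_timescale
        Autocorrelation scale of the random envelope, seconds.
    level_offset_db
        Level of this segment relative to the stimulus mean, dB.
    """

    duration: float
    band_low: float
    band_high: float
    modulation_depth: float = 0.5
    modulation_timescale: float = 0.05
    level_offset_db: float = 0.0
    name: str = ""

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be below band_high")
        if self.modulation_timescale <= 0:
            raise ValueError("modulation_timescale must be positive")


@dataclass
class Waveform:
    """Mono pressure-like waveform with its exact sampling rate."""

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


# Default segment table: seven textures whose total, with shared 460 ms
# transitions, is exactly 18.7 s.  Bands span the 300-4400 Hz range the
# downstream receptive fields cover; depths run from rain-like (weak)
# to sand-like (complete modulation).
_SEG_DURATION = (18.7 + 6 * 0.46) / 7  # ~3.0657 s
DEFAULT_CROSSFADE = 0.46

_DEFAULT_TABLE = [
    # name,      low,   high, depth, timescale, offset
    ("rain", 300.0, 4400.0, 0.20, 0.050, 0.0),
    ("brook", 400.0, 2500.0, 0.45, 0.080, 1.0),
    ("wind", 300.0, 1500.0, 0.55, 0.250, -2.0),
    ("leaves", 1500.0, 4400.0, 0.60, 0.040, 0.0),
    ("gravel", 800.0, 3500.0, 0.75, 0.020, 2.0),
    ("fire", 500.0, 3000.0, 0.85, 0.012, -1.0),
    ("sand", 1000.0, 4000.0, 1.00, 0.015, 0.0),
]


def default_segments() -> list:
    """The default seven-segment table (total stimulus length 18.7 s)."""
    return [
        SegmentSpec(
            duration=_SEG_DURATION,
            band_low=lo,
            band_high=hi,
            modulation_depth=d,
            modulation_timescale=ts,
            level_offset_db=off,
            name=name,
        )
        for name, lo, hi, d, ts, off in _DEFAULT_TABLE
    ]


def crossfade_weights(n: int) -> tuple:
    """cos^2 (outgoing) and sin^2 (incoming) amplitude weights over n samples.

    The phase runs from 0 to pi/2 inclusive, so weights sum to 1 at
    every sample and equal 0.5 at the temporal midpoint.
    """
    if n < 1:
        raise ValueError("crossfade must span at least one sample")
    theta = 0.5 * np.pi * np.linspace(0.0, 1.0, n)
    return np.cos(theta) ** 2, np.sin(theta) ** 2


def _bandpass_noise(n: int, low: float, high: float, sr: float, rng) -> np.ndarray:
    """Gaussian noise restricted to [low, high] Hz by an FFT brick wall."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / sr)
    spec[(f < low) | (f > high)] = 0.0
    return np.fft.irfft(spec, n)


def _random_envelope(n: int, timescale: float, depth: float, sr: float, rng,
                     env_rate: float = 2000.0) -> np.ndarray:
    """Log-normal low-pass envelope in (0, 1], mixed toward 1 by depth.

    Generated on a coarse grid (the envelope is band-limited far below
    ``env_rate``) and linearly interpolated to the audio rate.
    """
    n_env = max(int(np.ceil(n * env_rate / sr)) + 1, 4)
    sigma = max(timescale * env_rate, 1.0)
    z = gaussian_filter1d(rng.standard_normal(n_env), sigma, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    env = np.exp(z)
    env_norm = env / env.max()
    coarse = (1.0 - depth) + depth * env_norm
    t = np.arange(n) * (env_rate / sr)
    return np.interp(t, np.arange(n_env), coarse)


def synthesize_stimulus(
    segments,
    crossfade: float = DEFAULT_CROSSFADE,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
    headroom: float = 0.95,
) -> Waveform:
    """Render modulated-noise segments joined by cos^2 crossfades.

    Adjacent segments overlap during each transition, so the total
    duration is ``sum(durations) - (n_segments - 1) * crossfade``.
    During a transition the outgoing segment is weighted cos^2 and the
    incoming sin^2, summing to one at every sample.  The result is peak
    normalized to ``headroom``.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("at least one segment is required")
    if crossfade < 0:
        raise ValueError("crossfade must be nonnegative")
    if len(segments) > 1 and crossfade >= min(s.duration for s in segments):
        raise ValueError("crossfade must be shorter than the shortest segment")
    nyquist = sample_rate / 2
    for s in segments:
        if s.band_high >= nyquist:
            raise ValueError(f"segment {s.name!r}: band_high must be below Nyquist")

    rng = np.random.default_rng(seed)
    c = int(round(crossfade * sample_rate))
    rendered = []
    for s in segments:
        n = int(round(s.duration * sample_rate))
        carrier = _bandpass_noise(n, s.band_low, s.band_high, sample_rate, rng)
        rms = np.sqrt(np.mean(carrier**2))
        if rms > 0:
            carrier /= rms
        env = _random_envelope(n, s.modulation_timescale, s.modulation_depth, sample_rate, rng)
        rendered.append(carrier * env * 10 ** (s.level_offset_db / 20.0))

    total = sum(x.size for x in rendered) - (len(rendered) - 1) * c
    out = np.zeros(total)
    if c > 0 and len(rendered) > 1:
        w_out, w_in = crossfade_weights(c)
    pos = 0
    for k, x in enumerate(rendered):
        x = x.copy()
        if c > 0:
            if k > 0:
                x[:c] *= w_in
            if k < len(rendered) - 1:
                x[-c:] *= w_out
        out[pos : pos + x.size] += x
        pos += x.size - c
    peak = np.abs(out).max()
    if peak > 0:
        out *= headroom / peak
    return Waveform(out, sample_rate)
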