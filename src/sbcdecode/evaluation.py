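"""Reconstruction-quality diagnostics.

Covers the correlation decomposition (overall / temporal / spectral),
conditional level densities and their slopes and differences,
autocorrelation widths at relative heights, temporal modulation
spectra, across-frequency correlations and the Cohen's U1 nonoverlap
effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import welch

from .spectro import Spectrogram


def _values(spec) -> np.ndarray:
    return spec.values if isinstance(spec, Spectrogram) else np.asarray(spec, dtype=float)


def _frame_rate(spec, default=2000.0) -> float:
    return spec.frame_rate if isinstance(spec, Spectrogram) else default


@dataclass
class ReconQuality:
    """Correlation decomposition plus the dB spread of a reconstruction.

    ``variance_db`` is the standard deviation of the reconstructed dB
    values (the dB-scale spread of the reconstruction); the raw variance
    is its square.
    """

    correlation_overall: float
    correlation_temporal: float
    correlation_spectral: float
    variance_db: float


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def correlation_decomposition(real, recon) -> ReconQuality:
    """Overall, temporal and spectral correlation between spectrograms.

    overall: Pearson correlation over all (t, f) cells; temporal:
    per-band correlation over time averaged across bands; spectral:
    per-time-bin correlation across frequency averaged across bins.
    Zero-variance bands/bins are excluded from the averages.
    """
    A, B = _values(real), _values(recon)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    overall = _safe_corr(A.ravel(), B.ravel())
    temporal = np.nanmean([_safe_corr(A[:, f], B[:, f]) for f in range(A.shape[1])])
    spectral = np.nanmean([_safe_corr(A[t, :], B[t, :]) for t in range(A.shape[0])])
    return ReconQuality(overall, float(temporal), float(spectral), float(B.std()))


@dataclass
class CLD:
    """Conditional level density: column-stochastic joint level histogram.

    ``p_cond[i, j]`` is the probability of reconstructed-level bin i
    given real-level bin j; populated columns sum to one, empty columns
    are all-zero and listed in ``empty_columns``.
    """

    p_cond: np.ndarray  # (n_recon_bins, n_real_bins)
    level_bin_edges: np.ndarray  # dB, shared by both axes
    counts: np.ndarray
    empty_columns: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.level_bin_edges
        return 0.5 * (e[:-1] + e[1:])


def conditional_level_density(real, recon, bin_width: float = 1.0) -> CLD:
    """Joint (real, reconstructed) level histogram, column-normalized by
    the level distribution of the real stimulus."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    A, B = _values(real), _values(recon)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.std() == 0:
        warnings.warn("real spectrogram is constant; CLD has a single populated column")
    lo = min(A.min(), B.min())
    hi = max(A.max(), B.max())
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    counts, _, _ = np.histogram2d(B.ravel(), A.ravel(), bins=[edges, edges])
    col_sums = counts.sum(axis=0)
    p = np.zeros_like(counts)
    populated = col_sums > 0
    p[:, populated] = counts[:, populated] / col_sums[populated]
    return CLD(p, edges, counts, np.flatnonzero(~populated))


def cld_difference(a: CLD, b: CLD) -> np.ndarray:
    """Elementwise difference of two CLDs; columns of the result sum to 0
    wherever both inputs are populated."""
    if a.level_bin_edges.shape != b.level_bin_edges.shape or not np.allclose(
        a.level_bin_edges, b.level_bin_edges
    ):
        raise ValueError("CLDs must share identical level bin edges")
    return a.p_cond - b.p_cond


def cld_slope(real_levels, recon_levels, conf: float = 0.95):
    """OLS slope of reconstructed on real levels with a confidence interval.

    Returns ``(slope, (ci_low, ci_high))``.
    """
    x = np.asarray(real_levels, dtype=float).ravel()
    y = np.asarray(recon_levels, dtype=float).ravel()
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired level values")
    if x.std() == 0:
        raise ValueError("slope undefined: real levels have zero variance")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + conf / 2, x.size - 2)
    return res.slope, (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)


def autocorr_width(spec, relative_heights, max_lag: float = 0.1,
                   frame_rate: float = None):
    """Temporal autocorrelation width per relative height, band-averaged.

    Each band's mean-subtracted time course is autocorrelated and
    normalized to its zero-lag value; the width at height h is the full
    span (seconds) between the first crossings of h on either side of
    zero lag, with linear interpolation between lag samples.  Heights
    never crossed within ``max_lag`` give NaN with a warning.

    Returns an array aligned with ``relative_heights``.
    """
    heights = np.asarray(relative_heights, dtype=float)
    if np.any((heights <= 0) | (heights >= 1)):
        raise ValueError("relative heights must lie strictly in (0, 1)")
    V = _values(spec)
    fr = frame_rate if frame_rate is not None else _frame_rate(spec)
    n_lag = min(int(round(max_lag * fr)), V.shape[0] - 1)
    widths = np.full((V.shape[1], heights.size), np.nan)
    nfft = int(2 ** np.ceil(np.log2(2 * V.shape[0])))
    for f in range(V.shape[1]):
        x = V[:, f] - V[:, f].mean()
        if not np.any(x):
            continue
        spec_x = np.fft.rfft(x, nfft)
        ac = np.fft.irfft(spec_x * np.conj(spec_x), nfft)[: n_lag + 1]
        ac = ac / ac[0]
        for k, h in enumerate(heights):
            below = np.flatnonzero(ac < h)
            if below.size == 0:
                continue
            i = below[0]  # first lag sample below h
            # linear interpolation between samples i-1 and i
            frac = (ac[i - 1] - h) / (ac[i - 1] - ac[i]) if i > 0 else 0.0
            half = (i - 1 + frac) / fr
            widths[f, k] = 2.0 * half  # symmetric autocorrelation
    out = np.full(heights.size, np.nan)
    for k in range(heights.size):
        col = widths[:, k]
        if np.isnan(col).all():
            warnings.warn(
                f"autocorrelation never crossed height {heights[k]} within "
                f"{max_lag} s in any band"
            )
        else:
            if np.isnan(col).any():
                warnings.warn(
                    f"height {heights[k]}: {int(np.isnan(col).sum())} band(s) "
                    "never crossed; excluded from the average"
                )
            out[k] = np.nanmean(col)
    return out


def modulation_spectrum(spec, band=(100.0, 150.0), nperseg: int = None,
                        window: str = "hann", frame_rate: float = None):
    """Temporal modulation power spectrum of a spectrogram.

    Per frequency band, the PSD of the mean-subtracted dB time course
    (segment-averaged periodogram) is computed and averaged across
    bands.  Returns ``(mod_freqs, psd, band_power)`` where
    ``band_power`` integrates the PSD over the requested modulation
    band (e.g. the 100-150 Hz range emphasized by inhibition).
    """
    V = _values(spec)
    fr = frame_rate if frame_rate is not None else _frame_rate(spec)
    if band[1] > fr / 2:
        raise ValueError("modulation band exceeds the frame-rate Nyquist")
    if nperseg is None:
        nperseg = min(1024, V.shape[0])
    freqs, psd = welch(V - V.mean(axis=0), fs=fr, window=window,
                       nperseg=nperseg, detrend="constant", axis=0)
    psd_mean = psd.mean(axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    band_power = float(np.trapezoid(psd_mean[sel], freqs[sel])) if sel.sum() > 1 \
        else float(psd_mean[sel].sum())
    return freqs, psd_mean, band_power


def spectral_correlation(spec):
    """Across-frequency correlation versus frequency separation.

    For each separation ``df`` (in band steps) the zero-lag Pearson
    correlation over time between all band pairs at that separation is
    averaged; simultaneous (same-time-bin) values only.  ``df = 0``
    gives exactly 1.  Constant bands are excluded with a warning.

    Returns ``(separations, correlations)``.
    """
    V = _values(spec)
    if V.shape[1] < 2:
        raise ValueError("need at least 2 frequency bands")
    sds = V.std(axis=0)
    if np.any(sds == 0):
        warnings.warn(
            f"{int((sds == 0).sum())} constant band(s) excluded from "
            "spectral correlation"
        )
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(V.T)
    n = V.shape[1]
    seps = np.arange(n)
    out = np.full(n, np.nan)
    out[0] = 1.0
    for d in range(1, n):
        diag = np.diagonal(C, offset=d)
        if np.isfinite(diag).any():
            out[d] = np.nanmean(diag)
    return seps, out


def cohens_u1(group_a, group_b) -> float:
    """Cohen's U1 nonoverlap effect size.

    The fraction of all observations (both groups pooled) lying outside
    the overlap of the two groups' ranges; 0 for identical groups, 1
    for disjoint ones.  Symmetric in its arguments.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    lo = max(a.min(), b.min())
    hi = min(a.max(), b.max())
    if lo > hi:  # disjoint ranges
        return 1.0
    outside = np.count_nonzero((a < lo) | (a > hi)) + np.count_nonzero(
        (b < lo) | (b > hi)
    )
    return outside / (a.size + b.size)
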