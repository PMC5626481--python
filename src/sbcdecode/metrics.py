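"""Response statistics: rates, failure fractions, sparsity, reproducibility.

Sparsity is the variance-based lifetime statistic
``S = 1 - <r(t)>^2 / <r(t)^2>`` of a peri-stimulus rate; reproducibility
is the pair-averaged, rate-normalized lag-0 cross-correlation between
trials minus one, which is 0 in expectation for a fixed-rate Poisson
process and can exceed 1 for strongly locked responses.
"""

from __future__ import annotations

import warnings

import numpy as np

from .spiketrains import EventTrainSet, bin_unit_trials


def _window_or_full(events: EventTrainSet, window):
    if window is None:
        return 0.0, events.duration
    lo, hi = float(window[0]), float(window[1])
    if not 0.0 <= lo < hi <= events.duration + 1e-9:
        raise ValueError("window must be a nonempty interval inside the recording")
    return lo, hi


def firing_rate(events: EventTrainSet, stream: str = "anf", window=None) -> np.ndarray:
    """Trial-averaged firing rate in Hz, one value per unit."""
    lo, hi = _window_or_full(events, window)
    if hi - lo <= 0:
        raise ValueError("window length must be positive")
    rates = np.empty(events.n_units)
    for i, unit in enumerate(events.units):
        n = sum(
            np.count_nonzero((t >= lo) & (t < hi))
            for t in (unit.stream_times(j, stream) for j in range(unit.n_trials))
        )
        rates[i] = n / ((hi - lo) * max(unit.n_trials, 1))
    return rates


def failure_fraction(events: EventTrainSet, window=None) -> np.ndarray:
    """Fraction of events that failed to trigger a postsynaptic spike,
    pooled across trials, per unit.  Units with no event in the window
    yield NaN with a warning."""
    lo, hi = _window_or_full(events, window)
    out = np.empty(events.n_units)
    for i, unit in enumerate(events.units):
        n_tot = n_fail = 0
        for j in range(unit.n_trials):
            m = (unit.times[j] >= lo) & (unit.times[j] < hi)
            n_tot += int(m.sum())
            n_fail += int((~unit.success[j][m]).sum())
        if n_tot == 0:
            warnings.warn(f"unit {i}: no events in window; failure fraction undefined")
            out[i] = np.nan
        else:
            out[i] = n_fail / n_tot
    return out


def sparsity(psth, normalized: bool = False) -> float:
    """Variance-based sparsity of a nonnegative rate sequence.

    Returns ``1 - <r>^2 / <r^2>`` (time averages).  With
    ``normalized=True`` the value is divided by ``1 - 1/N`` so the upper
    bound is exactly 1 for any number of bins N.
    """
    r = np.asarray(psth, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("psth must be a 1-D sequence with at least 2 bins")
    if np.any(r < 0):
        raise ValueError("psth values must be nonnegative")
    m2 = np.mean(r**2)
    if m2 == 0:
        raise ValueError("sparsity undefined for an all-zero psth")
    s = 1.0 - np.mean(r) ** 2 / m2
    if normalized:
        s /= 1.0 - 1.0 / r.size
    return float(s)


def unit_psth(
    events: EventTrainSet, unit_index: int, stream: str = "anf",
    frame_rate: float = 2000.0,
) -> np.ndarray:
    """Trial-averaged rate over time (Hz) of one unit at the given frame rate."""
    unit = events.units[unit_index]
    counts = bin_unit_trials(unit, events.duration, stream, frame_rate)
    return counts.mean(axis=0) * frame_rate


def reproducibility(trial_counts, lag_range: int = 0):
    """Across-trial reproducibility of one unit's binned response.

    For every unordered pair of distinct trials the raw lag-0
    cross-correlation ``sum_t r_i(t) r_j(t)`` is divided by
    ``S_i * S_j / N_bins`` (spike-count product over bin count), the
    pair values are averaged, and 1 is subtracted.  Pairs involving an
    empty trial are excluded (their normalization is undefined) with a
    warning.  With ``lag_range > 0`` the full pair-averaged normalized
    correlogram for lags ``-lag_range..lag_range`` is returned alongside.

    Parameters
    ----------
    trial_counts : ndarray, shape (n_trials, n_bins)
        Per-trial binned counts, e.g. from
        :func:`sbcdecode.spiketrains.bin_unit_trials`.

    Returns
    -------
    float, or (float, ndarray) when ``lag_range > 0``.
    """
    r = np.asarray(trial_counts, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need a 2-D (trials x bins) array with >= 2 trials")
    n_bins = r.shape[1]
    s = r.sum(axis=1)
    keep = s > 0
    if not np.all(keep):
        warnings.warn(
            f"excluding {np.count_nonzero(~keep)} empty trial(s) from "
            "reproducibility (normalization undefined)"
        )
        r, s = r[keep], s[keep]
    n = r.shape[0]
    if n < 2:
        raise ValueError("fewer than 2 non-empty trials")
    # q_i = r_i / S_i; pair-averaged normalized lag-0 correlation is then
    # N_bins * sum_t sum_{i<j} q_i q_j / n_pairs
    q = r / s[:, None]
    tot = q.sum(axis=0)
    pair_sum = 0.5 * (np.sum(tot**2) - np.sum(q**2))
    n_pairs = n * (n - 1) / 2
    value = float(n_bins * pair_sum / n_pairs - 1.0)
    if lag_range <= 0:
        return value
    lags = np.arange(-lag_range, lag_range + 1)
    corr = np.zeros(lags.size)
    for i in range(n):
        for j in range(i + 1, n):
            full = np.correlate(q[i], q[j], mode="full")
            center = n_bins - 1
            corr += full[center - lag_range : center + lag_range + 1]
    corr = n_bins * corr / n_pairs - 1.0
    return value, corr


def metrics_table(
    events: EventTrainSet, frame_rate: float = 2000.0, window=None,
):
    """Tidy per-unit, per-stream summary (rate, failure fraction,
    sparsity, reproducibility) as a pandas DataFrame."""
    import pandas as pd

    lo, hi = _window_or_full(events, window)
    rows = []
    ff = failure_fraction(events, window=(lo, hi))
    for stream in ("anf", "sbc", "epsp_fail"):
        rates = firing_rate(events, stream, (lo, hi))
        for i, unit in enumerate(events.units):
            counts = bin_unit_trials(unit, events.duration, stream, frame_rate)
            b0, b1 = int(round(lo * frame_rate)), int(round(hi * frame_rate))
            counts = counts[:, b0:b1]
            psth = counts.mean(axis=0) * frame_rate
            try:
                sp = sparsity(psth)
            except ValueError:
                sp = np.nan
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rep = reproducibility(counts)
            except ValueError:
                rep = np.nan
            rows.append(
                dict(unit=i, cf=unit.cf, stream=stream, window_start=lo,
                     window_stop=hi, rate_hz=rates[i],
                     failure_fraction=ff[i] if stream == "anf" else np.nan,
                     sparsity=sp, reproducibility=rep)
            )
    return pd.DataFrame(rows)
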