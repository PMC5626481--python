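"""Linear stimulus reconstruction from population spike trains.

The decoder is the classical ridge-regularized normal-equation
estimator: with responses R(t, n) and stimulus spectrogram S(t, f), the
per-band kernels g_f(tau, n) solve

    g_f = (C_RR + lambda I)^{-1} C_RS_f,

and the reconstruction is the linear superposition
``S_hat(t, f) = sum_tau sum_n g_f(tau, n) R(t + tau, n)`` over a window
of response lags after the stimulus frame.  Features are standardized
and the Gram matrix normalized by the number of time bins, so the ridge
weight is relative to a unit-diagonal C_RR and scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .spectro import Spectrogram
from .spiketrains import BinnedResponse


def _response_matrix(R) -> np.ndarray:
    """(n_bins, n_units) float response matrix from array or container."""
    if isinstance(R, BinnedResponse):
        return R.counts.T.astype(float)
    R = np.asarray(R, dtype=float)
    if R.ndim != 2:
        raise ValueError("response must be 2-D")
    return R


def _target_matrix(S):
    if isinstance(S, Spectrogram):
        return S.values, S
    return np.asarray(S, dtype=float), None


def lagged_design(X: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Stack lagged copies of the response: column block k holds
    ``X[t + taus[k], :]``, zero-padded outside the recording."""
    T, U = X.shape
    out = np.zeros((T, taus.size * U))
    for k, tau in enumerate(taus):
        if tau >= 0:
            if tau < T:
                out[: T - tau, k * U : (k + 1) * U] = X[tau:, :]
        else:
            if -tau < T:
                out[-tau:, k * U : (k + 1) * U] = X[: T + tau, :]
    return out


@dataclass
class ReconstructionKernel:
    """Frozen decoder state: per-band (lag x unit) weights plus the
    standardization needed to apply them."""

    weights: np.ndarray  # (n_freqs, n_lags, n_units)
    lag_axis: np.ndarray  # seconds
    taus: np.ndarray  # lags in bins
    ridge_lambda: float
    feature_means: np.ndarray
    feature_scales: np.ndarray
    intercept: np.ndarray  # per-band mean, dB
    frame_rate: float
    freq_axis: np.ndarray = None


class SpectrogramDecoder(BaseEstimator, RegressorMixin):
    """Ridge-regularized linear decoder of a spectrogram from spike counts.

    Parameters
    ----------
    lag_window : (float, float)
        Response lags used to predict the stimulus at time t, in
        seconds after the stimulus frame; default (0, 0.025) covers
        response latencies and the ~10 ms inhibitory time constant.
    ridge_lambda : float
        Ridge weight applied to the unit-diagonal (standardized,
        bin-normalized) response Gram matrix; default 0.1.
    frame_rate : float
        Shared response/spectrogram frame rate in Hz.
    standardize : bool
        Center and scale each unit-lag feature to unit variance.
    center_targets : bool
        Remove (and re-add on prediction) the per-band mean.

    Attributes
    ----------
    coef_ : ndarray (n_features, n_freqs)
        Kernel weights on the standardized design.
    kernel_ : ReconstructionKernel
        The same weights with axes and standardization bundled.
    intercept_ : ndarray (n_freqs,)
    """

    def __init__(self, lag_window=(0.0, 0.025), ridge_lambda=0.1,
                 frame_rate=2000.0, standardize=True, center_targets=True):
        self.lag_window = lag_window
        self.ridge_lambda = ridge_lambda
        self.frame_rate = frame_rate
        self.standardize = standardize
        self.center_targets = center_targets

    def _taus(self) -> np.ndarray:
        t0 = int(round(self.lag_window[0] * self.frame_rate))
        t1 = int(round(self.lag_window[1] * self.frame_rate))
        if t1 < t0:
            raise ValueError("empty lag window")
        return np.arange(t0, t1 + 1)

    def fit(self, R, S):
        """Estimate kernels from responses R and spectrogram S.

        R : BinnedResponse or array (n_bins, n_units); S : Spectrogram
        or array (n_bins, n_freqs), on the same frame grid.
        """
        X = _response_matrix(R)
        Y, spec = _target_matrix(S)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"response ({X.shape[0]} bins) and spectrogram ({Y.shape[0]} "
                "bins) must share the time grid"
            )
        self.n_units_ = X.shape[1]
        taus = self._taus()
        D = lagged_design(X, taus)
        if not np.any(D):
            import warnings

            warnings.warn("all-zero response; decoder reduces to the intercept")
        self._fit_scaling(D)
        Ds = (D - self.feature_means_) / self.feature_scales_
        self.intercept_ = Y.mean(axis=0) if self.center_targets else np.zeros(Y.shape[1])
        Yc = Y - self.intercept_
        T = D.shape[0]
        G = Ds.T @ Ds / T + self.ridge_lambda * np.eye(Ds.shape[1])
        B = Ds.T @ Yc / T
        try:
            self.coef_ = np.linalg.solve(G, B)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "normal equations singular even with ridge term; responses "
                "are likely degenerate (all-zero or perfectly collinear)"
            ) from err
        self.taus_ = taus
        self.freq_axis_ = spec.freq_axis if spec is not None else None
        self._template_spec = spec
        return self

    def _fit_scaling(self, D: np.ndarray):
        if self.standardize:
            self.feature_means_ = D.mean(axis=0)
            sd = D.std(axis=0)
            sd[sd == 0] = 1.0  # dead features carry zero weight anyway
            self.feature_scales_ = sd
        else:
            self.feature_means_ = np.zeros(D.shape[1])
            self.feature_scales_ = np.ones(D.shape[1])

    @property
    def kernel_(self) -> ReconstructionKernel:
        n_lags = self.taus_.size
        w = self.coef_.T.reshape(-1, n_lags, self.n_units_)
        return ReconstructionKernel(
            weights=w, lag_axis=self.taus_ / self.frame_rate, taus=self.taus_,
            ridge_lambda=self.ridge_lambda, feature_means=self.feature_means_,
            feature_scales=self.feature_scales_, intercept=self.intercept_,
            frame_rate=self.frame_rate, freq_axis=self.freq_axis_,
        )

    def predict(self, R):
        """Reconstruct the spectrogram (n_bins, n_freqs) from responses."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("decoder is not fitted")
        X = _response_matrix(R)
        if X.shape[1] != self.n_units_:
            raise ValueError(
                f"decoder was fitted on {self.n_units_} units, got {X.shape[1]}"
            )
        D = lagged_design(X, self.taus_)
        Ds = (D - self.feature_means_) / self.feature_scales_
        return Ds @ self.coef_ + self.intercept_

    def predict_spectrogram(self, R) -> Spectrogram:
        """Like :meth:`predict` but wrapped as a Spectrogram (requires the
        training target to have been a Spectrogram)."""
        if self._template_spec is None:
            raise ValueError("fit() target was a bare array; no axes to carry over")
        tpl = self._template_spec
        return Spectrogram(self.predict(R), tpl.freq_axis, tpl.frame_rate,
                           tpl.window_samples, tpl.source_rate)


def estimate_kernels(R, S, lag_window=(0.0, 0.025), ridge_lambda=0.1,
                     frame_rate=2000.0, **kw) -> ReconstructionKernel:
    """Fit a :class:`SpectrogramDecoder` and return its kernel bundle."""
    dec = SpectrogramDecoder(lag_window=lag_window, ridge_lambda=ridge_lambda,
                             frame_rate=frame_rate, **kw)
    dec.fit(R, S)
    return dec.kernel_


def reconstruct(R, kernels: ReconstructionKernel) -> np.ndarray:
    """Apply estimated kernels to responses (thin wrapper over the
    decoder's linear superposition)."""
    X = _response_matrix(R)
    n_freqs, n_lags, n_units = kernels.weights.shape
    if X.shape[1] != n_units:
        raise ValueError(f"kernels expect {n_units} units, got {X.shape[1]}")
    D = lagged_design(X, kernels.taus)
    Ds = (D - kernels.feature_means) / kernels.feature_scales
    coef = kernels.weights.reshape(n_freqs, -1).T
    return Ds @ coef + kernels.intercept


def _section_bounds(n_bins: int, n_sections: int) -> list:
    edges = np.linspace(0, n_bins, n_sections + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_sections)]


@dataclass
class CrossValReport:
    """Per-section reconstruction quality plus in-sample counterpart.

    ``sections`` is a tidy DataFrame (one row per held-out section),
    ``insample`` a single-row dict, and ``summary`` the average of the
    cross-validated section means with the in-sample values.
    """

    sections: pd.DataFrame
    insample: dict
    summary: dict = field(default_factory=dict)


def crossval_reconstruct(R, S, n_sections: int = 10, lag_window=(0.0, 0.025),
                         ridge_lambda: float = 0.1, frame_rate: float = 2000.0):
    """Cross-validated reconstruction over contiguous time sections.

    The recording is split into ``n_sections`` contiguous equal blocks;
    kernels trained on all other blocks predict each held-out block and
    the stitched prediction is returned together with a
    :class:`CrossValReport` whose summary averages the cross-validated
    and in-sample quality estimates.
    """
    from .evaluation import correlation_decomposition

    if n_sections < 2:
        raise ValueError("need at least 2 cross-validation sections")
    X = _response_matrix(R)
    Y, spec = _target_matrix(S)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("response and spectrogram must share the time grid")
    T = X.shape[0]
    bounds = _section_bounds(T, n_sections)
    dec = SpectrogramDecoder(lag_window=lag_window, ridge_lambda=ridge_lambda,
                             frame_rate=frame_rate)
    taus = dec._taus()
    if min(b1 - b0 for b0, b1 in bounds) <= taus.size:
        raise ValueError("cross-validation sections shorter than the lag window")
    D = lagged_design(X, taus)
    # standardization from the full recording so per-fold Gram matrices
    # can be assembled by subtraction
    dec._fit_scaling(D)
    Ds = (D - dec.feature_means_) / dec.feature_scales_
    nf = Ds.shape[1]
    G_parts = [Ds[b0:b1].T @ Ds[b0:b1] for b0, b1 in bounds]
    B_parts = [Ds[b0:b1].T @ Y[b0:b1] for b0, b1 in bounds]
    y_sums = [Y[b0:b1].sum(axis=0) for b0, b1 in bounds]
    G_all = np.sum(G_parts, axis=0)
    B_all = np.sum(B_parts, axis=0)
    y_all = np.sum(y_sums, axis=0)

    d_sums = [Ds[b0:b1].sum(axis=0) for b0, b1 in bounds]
    d_all = np.sum(d_sums, axis=0)

    recon = np.empty_like(Y)
    rows = []
    for s, (b0, b1) in enumerate(bounds):
        T_tr = T - (b1 - b0)
        mu = (y_all - y_sums[s]) / T_tr  # training target mean per band
        m_tr = (d_all - d_sums[s]) / T_tr  # training feature means
        # Gram/cross terms of the per-fold centered design, assembled from
        # the precomputed per-section raw moments
        G = (G_all - G_parts[s] - T_tr * np.outer(m_tr, m_tr)) / T_tr \
            + ridge_lambda * np.eye(nf)
        B = (B_all - B_parts[s] - T_tr * np.outer(m_tr, mu)) / T_tr
        coef = np.linalg.solve(G, B)
        pred = (Ds[b0:b1] - m_tr) @ coef + mu
        recon[b0:b1] = pred
        q = correlation_decomposition(Y[b0:b1], pred)
        rows.append(dict(section=s, kind="crossval",
                         correlation_overall=q.correlation_overall,
                         correlation_temporal=q.correlation_temporal,
                         correlation_spectral=q.correlation_spectral,
                         variance_db=q.variance_db))
    dec.fit(X, Y)
    pred_in = dec.predict(X)
    q_in = correlation_decomposition(Y, pred_in)
    insample = dict(correlation_overall=q_in.correlation_overall,
                    correlation_temporal=q_in.correlation_temporal,
                    correlation_spectral=q_in.correlation_spectral,
                    variance_db=q_in.variance_db)
    sections = pd.DataFrame(rows)
    summary = {
        k: 0.5 * (sections[k].mean() + insample[k])
        for k in ("correlation_overall", "correlation_temporal",
                  "correlation_spectral", "variance_db")
    }
    report = CrossValReport(sections=sections, insample=insample, summary=summary)
    if spec is not None:
        recon = Spectrogram(recon, spec.freq_axis, spec.frame_rate,
                            spec.window_samples, spec.source_rate)
    return recon, report
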