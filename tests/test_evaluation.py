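"""Reconstruction diagnostics: correlations, CLDs, widths, spectra, U1."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import sbcdecode as sd


# ------------------------------------------------ correlation decomposition
def test_decomposition_identity_and_offset_invariance():
    rng = np.random.default_rng(0)
    A = rng.standard_normal((50, 8))
    q = sd.correlation_decomposition(A, A)
    assert q.correlation_overall == pytest.approx(1.0)
    assert q.correlation_temporal == pytest.approx(1.0)
    assert q.correlation_spectral == pytest.approx(1.0)
    q2 = sd.correlation_decomposition(A, A + 3.0)
    assert q2.correlation_overall == pytest.approx(1.0)
    assert q2.variance_db == pytest.approx(A.std())


def test_decomposition_band_mean_replacement_hand_case():
    # 3 time bins x 4 bands; recon = per-band time means -> zero temporal
    # variance per band (excluded); spectral corr = corr of the band-mean
    # profile with the real rows.
    A = np.array([[0.0, 1.0, 2.0, 4.0],
                  [1.0, 3.0, 2.0, 0.0],
                  [2.0, 2.0, 2.0, 2.0]])
    B = np.tile(A.mean(axis=0), (3, 1))
    q = sd.correlation_decomposition(A, B)
    assert np.isnan(q.correlation_temporal)
    expected = np.nanmean([
        np.corrcoef(A[t], A.mean(axis=0))[0, 1] if A[t].std() > 0 else np.nan
        for t in range(3)
    ])
    assert q.correlation_spectral == pytest.approx(expected)


def test_decomposition_shape_mismatch():
    with pytest.raises(ValueError):
        sd.correlation_decomposition(np.zeros((3, 2)), np.zeros((2, 3)))


# ----------------------------------------------------------------- CLD
def test_cld_identity_concentrates_on_diagonal():
    rng = np.random.default_rng(1)
    A = rng.uniform(0, 30, size=(40, 10))
    cld = sd.conditional_level_density(A, A, bin_width=1.0)
    populated = np.setdiff1d(np.arange(cld.p_cond.shape[1]), cld.empty_columns)
    sums = cld.p_cond[:, populated].sum(axis=0)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert np.allclose(cld.p_cond[:, populated].argmax(axis=0), populated)


def test_cld_affine_compression_slope():
    rng = np.random.default_rng(2)
    A = rng.uniform(-30, 30, size=(100, 22))
    B = 0.5 * A
    slope, ci = sd.cld_slope(A.ravel(), B.ravel())
    assert slope == pytest.approx(0.5, abs=1e-9)
    cld = sd.conditional_level_density(A, B, bin_width=1.0)
    # mass lies on a line of slope 0.5: recon bin center ~ 0.5 * real center
    populated = np.setdiff1d(np.arange(cld.p_cond.shape[1]), cld.empty_columns)
    centers = cld.bin_centers
    recon_mean = cld.p_cond[:, populated].T @ centers
    fit = np.polyfit(centers[populated], recon_mean, 1)
    assert fit[0] == pytest.approx(0.5, abs=0.05)


def test_cld_difference_columns_sum_to_zero_and_antisymmetry():
    rng = np.random.default_rng(3)
    A = rng.uniform(0, 20, size=(60, 5))
    B1, B2 = A + rng.normal(0, 2, A.shape), A + rng.normal(0, 2, A.shape)
    lo = min(A.min(), B1.min(), B2.min())
    hi = max(A.max(), B1.max(), B2.max())
    # shared edges via identical data ranges
    a = sd.conditional_level_density(np.clip(A, lo, hi), np.clip(B1, lo, hi))
    b = sd.conditional_level_density(np.clip(A, lo, hi), np.clip(B2, lo, hi))
    if a.level_bin_edges.size == b.level_bin_edges.size and np.allclose(
        a.level_bin_edges, b.level_bin_edges
    ):
        d = sd.cld_difference(a, b)
        both = np.setdiff1d(
            np.arange(d.shape[1]), np.union1d(a.empty_columns, b.empty_columns)
        )
        assert np.allclose(d[:, both].sum(axis=0), 0.0, atol=1e-9)
        assert np.allclose(d, -sd.cld_difference(b, a))
    zero = sd.cld_difference(a, a)
    assert np.allclose(zero, 0.0)


def test_cld_difference_requires_matching_edges():
    A = np.random.default_rng(4).uniform(0, 10, (20, 3))
    a = sd.conditional_level_density(A, A, bin_width=1.0)
    b = sd.conditional_level_density(A, A, bin_width=2.0)
    with pytest.raises(ValueError):
        sd.cld_difference(a, b)


def test_cld_constant_real_warns():
    with pytest.warns(UserWarning):
        sd.conditional_level_density(np.zeros((10, 2)), np.ones((10, 2)))


def test_cld_slope_cases():
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 10, 500)
    slope, ci = sd.cld_slope(x, x)
    assert slope == pytest.approx(1.0) and ci[0] <= 1.0 <= ci[1]
    slope2, _ = sd.cld_slope(x, 0.6 * x + rng.normal(0, 1e-6, 500))
    assert slope2 == pytest.approx(0.6, abs=1e-3)
    slope3, _ = sd.cld_slope(x, rng.uniform(0, 10, 500))
    assert abs(slope3) < 0.15
    with pytest.raises(ValueError):
        sd.cld_slope(np.ones(10), np.arange(10))


# ------------------------------------------------------- autocorr width
def test_autocorr_width_gaussian_bump():
    """Gaussian band time courses of sigma = 5 ms give an autocorrelation
    of sigma*sqrt(2); full width at half height = 2*sigma*sqrt(2*ln 2)*sqrt(2)."""
    fr, sigma = 2000.0, 0.005
    t = np.arange(8000) / fr
    bump = np.exp(-0.5 * ((t - 2.0) / sigma) ** 2)
    V = np.tile(bump[:, None], (1, 3))
    w = sd.autocorr_width(V, [0.5], frame_rate=fr)
    expected = 2 * sigma * np.sqrt(2) * np.sqrt(2 * np.log(2))
    assert w[0] == pytest.approx(expected, rel=0.03)


def test_autocorr_width_white_noise_is_narrow():
    rng = np.random.default_rng(6)
    V = rng.standard_normal((5000, 4))
    w = sd.autocorr_width(V, [0.3, 0.7], frame_rate=2000.0)
    assert np.all(w <= 2 / 2000.0)


def test_autocorr_width_monotone_in_height():
    rng = np.random.default_rng(7)
    x = np.convolve(rng.standard_normal(6000), np.ones(50) / 50, mode="same")
    V = x[:, None]
    heights = [0.2, 0.4, 0.6, 0.8]
    w = sd.autocorr_width(V, heights, frame_rate=2000.0)
    valid = ~np.isnan(w)
    assert np.all(np.diff(w[valid]) <= 1e-12)


def test_autocorr_width_never_crossed_warns_nan():
    t = np.arange(2000) / 2000.0
    V = np.sin(2 * np.pi * 0.1 * t)[:, None] + 10  # period >> max_lag
    with pytest.warns(UserWarning):
        w = sd.autocorr_width(V, [0.1], max_lag=0.05, frame_rate=2000.0)
    assert np.isnan(w[0])


def test_autocorr_width_rejects_bad_heights():
    with pytest.raises(ValueError):
        sd.autocorr_width(np.zeros((10, 1)), [1.5])


# ------------------------------------------------------ modulation spectrum
def test_modulation_spectrum_sinusoid_peak():
    fr = 2000.0
    t = np.arange(8192) / fr
    V = np.sin(2 * np.pi * 120.0 * t)[:, None] * np.ones((1, 3))
    freqs, psd, band_power = sd.modulation_spectrum(V, band=(100, 150),
                                                    frame_rate=fr)
    assert abs(freqs[np.argmax(psd)] - 120.0) < 2.0
    total = np.trapezoid(psd, freqs)
    assert band_power / total > 0.95


def test_modulation_spectrum_constant_is_zero():
    _, psd, band_power = sd.modulation_spectrum(np.full((4096, 2), 7.0),
                                                frame_rate=2000.0)
    assert np.allclose(psd, 0.0) and band_power == 0.0


def test_modulation_spectrum_parseval():
    rng = np.random.default_rng(8)
    V = rng.standard_normal((4096, 3))
    freqs, psd, _ = sd.modulation_spectrum(V, band=(100, 150), frame_rate=2000.0,
                                           nperseg=4096, window="boxcar")
    df = freqs[1] - freqs[0]
    var = np.mean([c.var() for c in V.T])
    assert np.sum(psd) * df == pytest.approx(var, rel=0.01)


def test_modulation_band_above_nyquist_rejected():
    with pytest.raises(ValueError):
        sd.modulation_spectrum(np.zeros((100, 2)), band=(900, 1100),
                               frame_rate=1000.0)


# ------------------------------------------------------ spectral correlation
def test_spectral_correlation_comodulated_bands():
    rng = np.random.default_rng(9)
    x = rng.standard_normal(3000)
    V = np.tile(x[:, None], (1, 6)) + np.linspace(0, 5, 6)  # identical courses
    seps, corr = sd.spectral_correlation(V)
    assert corr[0] == 1.0
    assert np.allclose(corr[1:], 1.0, atol=1e-9)


def test_spectral_correlation_independent_bands_near_zero():
    vals = []
    for s in range(10):
        V = np.random.default_rng(s).standard_normal((4000, 8))
        _, corr = sd.spectral_correlation(V)
        vals.append(np.nanmean(corr[1:]))
    assert abs(np.mean(vals)) < 0.05


def test_spectral_correlation_constant_band_excluded():
    rng = np.random.default_rng(10)
    V = rng.standard_normal((500, 3))
    V[:, 1] = 4.0
    with pytest.warns(UserWarning):
        _, corr = sd.spectral_correlation(V)
    assert corr[0] == 1.0


# ------------------------------------------------------------- Cohen's U1
@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([1, 2, 3], [10, 11], 1.0),
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 2, 3], [3, 4, 5], 4 / 6),
    ],
)
def test_cohens_u1_values(a, b, expected):
    assert sd.cohens_u1(a, b) == pytest.approx(expected)


@settings(derandomize=True, max_examples=50)
@given(
    arrays(float, st.integers(1, 20), elements=st.floats(-100, 100)),
    arrays(float, st.integers(1, 20), elements=st.floats(-100, 100)),
)
def test_cohens_u1_bounds_and_symmetry(a, b):
    v = sd.cohens_u1(a, b)
    assert 0.0 <= v <= 1.0
    assert sd.cohens_u1(b, a) == pytest.approx(v)
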