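"""Subtractive-inhibition model: integration, sigmoid, deletion, fitting."""

import numpy as np
import pytest

import sbcdecode as sd
from sbcdecode.inhibition import simulate_failure_fraction
from sbcdecode.spiketrains import bin_unit_trials

FR = 2000.0


# ------------------------------------------------------------- integration
def test_integration_of_zero_is_zero():
    assert np.all(sd.integrate_history(np.zeros(100), FR) == 0)


def test_integration_impulse_delay_and_decay():
    tau, dtc = 3e-3, 2e-3
    psth = np.zeros(200)
    psth[50] = 1.0
    ai = sd.integrate_history(psth, FR, delta_tc=dtc, tau_i=tau)
    peak = np.argmax(ai)
    assert peak == 50 + round(dtc * FR)
    k = round(tau * FR)  # decay by factor e over tau
    assert ai[peak + k] / ai[peak] == pytest.approx(np.exp(-1), rel=1e-9)


def test_integration_constant_rate_steady_state():
    r = 120.0
    ai = sd.integrate_history(np.full(2000, r), FR, delta_tc=0.0)
    assert ai[-1] == pytest.approx(r, rel=1e-6)  # unit-area kernel


# ------------------------------------------------------------------ sigmoid
def test_sigmoid_midpoint_saturation_and_value():
    assert sd.sigmoid_inhibition_rate(np.array([2.0]), i0=100, offset=2.0)[0] == 50.0
    assert sd.sigmoid_inhibition_rate(np.array([1e9]), i0=100, offset=0.0)[0] == pytest.approx(100.0)
    # S = 5, AI - O = 1 -> I0 / (1 + e^-5)
    v = sd.sigmoid_inhibition_rate(np.array([1.0]), i0=1.0, slope=5.0, offset=0.0)[0]
    assert v == pytest.approx(1 / (1 + np.exp(-5)), rel=1e-9)
    ai = np.linspace(-10, 10, 201)
    si = sd.sigmoid_inhibition_rate(ai, i0=7.0)
    assert np.all(np.diff(si) >= 0) and si.min() >= 0 and si.max() <= 7.0


# ------------------------------------------------- spontaneous failures
def test_spontaneous_failures_extremes(small_events):
    unit = small_events.units[0]
    same = sd.apply_spontaneous_failures(unit, 0.0, seed=0)
    for a, b in zip(same.success, unit.success):
        assert np.array_equal(a, b)
    allfail = sd.apply_spontaneous_failures(unit, 1.0, seed=0)
    assert not any(s.any() for s in allfail.success)


def test_spontaneous_failures_binomial_rate():
    n = 10_000
    t = np.linspace(0.001, 9.999, n)
    unit = sd.UnitTrains(cf=1000, times=[t], success=[np.ones(n, bool)])
    out = sd.apply_spontaneous_failures(unit, 0.36, seed=1)
    n_fail = int((~out.success[0]).sum())
    se = np.sqrt(n * 0.36 * 0.64)
    assert abs(n_fail - 3600) < 3 * se


# ------------------------------------------------------- spike deletion
def _poisson_unit(rate, T, n_trials, seed):
    rng = np.random.default_rng(seed)
    times = [np.sort(rng.uniform(0, T, rng.poisson(rate * T))) for _ in range(n_trials)]
    return sd.UnitTrains(cf=1000, times=times,
                         success=[np.ones(t.size, bool) for t in times])


def test_zero_inhibition_is_identity():
    unit = _poisson_unit(50, 2.0, 4, 0)
    out = sd.apply_subtractive_inhibition(unit, np.zeros(4000), FR, 2.0, seed=1)
    assert all(s.all() for s in out.success)


def test_saturating_inhibition_empties_sbc_stream():
    unit = _poisson_unit(50, 2.0, 4, 0)
    si = np.full(4000, 1e6)
    out = sd.apply_subtractive_inhibition(unit, si, FR, 2.0, seed=1)
    assert not any(s.any() for s in out.success)


def test_deletion_preserves_event_times():
    unit = _poisson_unit(80, 2.0, 5, 2)
    si = np.full(4000, 40.0)
    out = sd.apply_subtractive_inhibition(unit, si, FR, 2.0, seed=3)
    for a, b in zip(out.times, unit.times):
        assert np.array_equal(a, b)
    # ANF stream (all events) unchanged, only labels flipped
    total_before = sum(t.size for t in unit.times)
    total_after = sum(t.size for t in out.times)
    assert total_before == total_after


def test_deletion_uniform_across_trial_pool():
    # 3 events in one bin, quota 2: each survives with prob 1/3
    times = [[0.00012], [0.00015], [0.00018]]
    labels = [[True]] * 3
    si = np.zeros(2000)
    si[0] = 2 * FR / 3  # quota = si * n_trials / fr = 2 exactly
    survived = np.zeros(3)
    n_rep = 1000
    for s in range(n_rep):
        unit = sd.UnitTrains(cf=1000, times=times, success=labels)
        out = sd.apply_subtractive_inhibition(unit, si, FR, 1.0, seed=s)
        for j in range(3):
            survived[j] += out.success[j][0]
    p, se = 1 / 3, np.sqrt((1 / 3) * (2 / 3) / n_rep)
    for j in range(3):
        assert abs(survived[j] / n_rep - p) < 3 * se


def test_misaligned_si_rejected():
    unit = _poisson_unit(50, 2.0, 2, 0)
    with pytest.raises(ValueError):
        sd.apply_subtractive_inhibition(unit, np.zeros(123), FR, 2.0, seed=0)


def test_monotonicity_in_i0():
    """Raising I0 never increases the expected SBC count."""
    unit = _poisson_unit(100, 2.0, 5, 7)
    counts = bin_unit_trials(unit, 2.0, "anf", FR)
    psth = counts.mean(axis=0) * FR
    ai = sd.integrate_history(psth, FR)
    means = []
    for i0 in (0.0, 30.0, 80.0, 200.0):
        si = sd.sigmoid_inhibition_rate(ai, i0=i0, offset=80.0)
        fracs = [
            simulate_failure_fraction(counts, si, 0.0, FR,
                                      np.random.default_rng(s))
            for s in range(60)
        ]
        means.append(np.mean(fracs))  # failure fraction ~ deleted share
    assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))


def test_instantaneous_limit_matches_closed_form():
    """tau_i -> 0, delta_tc = 0, deterministic rounding: per-bin
    subtraction of a sigmoid of the instantaneous rate."""
    r = 200.0  # exactly r/FR counts per bin per trial on a regular train
    n_trials, T = 10, 1.0
    nb = int(T * FR)
    per_bin = int(r / FR * n_trials)  # 1 count per bin across the pool
    times, labels = [], []
    for j in range(n_trials):
        # one spike per 10 bins, staggered so each bin holds exactly one
        t = (np.arange(j, nb, n_trials) + 0.5) / FR
        times.append(t)
        labels.append(np.ones(t.size, bool))
    unit = sd.UnitTrains(cf=1000, times=times, success=labels)
    counts = bin_unit_trials(unit, T, "anf", FR)
    assert np.all(counts.sum(axis=0) == per_bin)
    psth = counts.mean(axis=0) * FR
    ai = sd.integrate_history(psth, FR, delta_tc=0.0, tau_i=1e-9)
    assert np.allclose(ai[1:], r)
    i0, off = 150.0, 100.0
    si = sd.sigmoid_inhibition_rate(ai, i0=i0, offset=off)
    out = sd.apply_subtractive_inhibition(unit, si, FR, T, seed=0,
                                          rounding="deterministic")
    expected_del_per_bin = round(i0 / (1 + np.exp(-5 * (r - off))) * n_trials / FR)
    n_deleted = sum(int((~s).sum()) for s in out.success)
    assert n_deleted == pytest.approx(expected_del_per_bin * (nb - 1), rel=0.01)


# ------------------------------------------------------------------ fitting
def test_degenerate_targets_select_zero_i0():
    unit = _poisson_unit(100, 4.0, 8, 11)
    est = sd.SubtractiveInhibition(i0_grid=11, offset_grid=11, random_state=0)
    est.fit(unit, 4.0, target_fail_spont=0.4, target_fail_driven=0.4)
    assert est.params_.i0 == pytest.approx(0.0)
    assert est.achieved_driven_ == pytest.approx(0.4, abs=0.02)


def test_fit_self_consistency_recovers_driven_fraction():
    """A unit relabelled with known (I0*, O*) is re-fit; the fitted model
    reproduces the observed driven failure fraction."""
    unit = _poisson_unit(130, 6.0, 10, 21)
    true = sd.InhibitionParams(i0=120.0, offset=120.0, p_spont_fail=0.3)
    relabelled = sd.apply_inhibition(unit, 6.0, true, seed=5)
    target = sd.failure_fraction(sd.EventTrainSet([relabelled], 6.0))[0]
    est = sd.SubtractiveInhibition(i0_grid=21, i0_max=250, offset_grid=21,
                                   n_fit_seeds=2, random_state=1)
    est.fit(unit, 6.0, target_fail_spont=0.3, target_fail_driven=target)
    assert est.achieved_driven_ == pytest.approx(target, abs=0.02)


def test_fit_validates_targets_and_grid():
    unit = _poisson_unit(50, 1.0, 3, 0)
    est = sd.SubtractiveInhibition(i0_grid=[], random_state=0)
    with pytest.raises(ValueError):
        est.fit(unit, 1.0)
    est = sd.SubtractiveInhibition(random_state=0)
    with pytest.raises(ValueError):
        est.fit(unit, 1.0, target_fail_driven=1.5)


def test_transform_requires_fit():
    unit = _poisson_unit(50, 1.0, 3, 0)
    with pytest.raises(RuntimeError):
        sd.SubtractiveInhibition().transform(unit, 1.0)


def test_sklearn_params_roundtrip():
    est = sd.SubtractiveInhibition(tau_i=5e-3)
    assert est.get_params()["tau_i"] == 5e-3
    est.set_params(slope=7.0)
    assert est.slope == 7.0
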