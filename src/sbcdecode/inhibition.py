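"""Activity-dependent subtractive inhibition at the endbulb synapse.

The model converts ANF input trains into SBC output trains purely by
relabelling events (success -> failure); no event is moved or created.
Two stages act in order:

1. spontaneous failures: each success event is independently relabelled
   with probability ``p_spont_fail``;
2. rate-dependent inhibition: the unit's trial-averaged ANF rate is
   delayed by ``delta_tc``, low-pass filtered with a unit-area
   exponential kernel of time constant ``tau_i`` (giving the integrated
   activity AI(t), in Hz), passed through the sigmoid
   ``SI(t) = I0 / (1 + exp(-slope * (AI(t) - O)))``, and ``SI(t) *
   n_trials / frame_rate`` events per time bin are relabelled, chosen
   uniformly at random across trials.  If a bin holds fewer successes
   than the quota, all of them are relabelled.

Per-cell parameters ``(I0, O)`` are fitted by exhaustive grid search on
the simulated driven failure fraction; the delay, time constant and
sigmoid slope are shared across cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit
from sklearn.base import BaseEstimator

from .spiketrains import (
    UnitTrains,
    _bin_indices,
    bin_unit_trials,
    n_bins_for,
)


@dataclass(frozen=True)
class InhibitionParams:
    """Parameters of the subtractive-inhibition model for one cell.

    delta_tc
        Conduction delay of the inhibitory pathway, seconds.
    tau_i
        Time constant of the exponential integration kernel, seconds.
    slope
        Inverse slope of the sigmoid activation (dimensionless).
    i0
        Maximal instantaneous subtracted rate, Hz.
    offset
        Integrated activity AI at which the sigmoid reaches I0/2; same
        units as AI (Hz, since the kernel has unit area).
    p_spont_fail
        Spontaneous failure probability per event.
    """

    delta_tc: float = 0.5e-3
    tau_i: float = 3e-3
    slope: float = 5.0
    i0: float = 0.0
    offset: float = 0.0
    p_spont_fail: float = 0.0

    def __post_init__(self):
        if self.tau_i <= 0:
            raise ValueError("tau_i must be positive")
        if self.i0 < 0:
            raise ValueError("i0 must be nonnegative")
        if not 0.0 <= self.p_spont_fail <= 1.0:
            raise ValueError("p_spont_fail must lie in [0, 1]")
        if self.delta_tc < 0:
            raise ValueError("delta_tc must be nonnegative")


def integrate_history(
    psth: np.ndarray, frame_rate: float, delta_tc: float = 0.5e-3,
    tau_i: float = 3e-3,
) -> np.ndarray:
    """Delayed exponential integration of a rate sequence.

    ``AI(t) = sum_{u>=0} w(u) * psth(t - delta_tc - u)`` with a
    unit-area discrete exponential kernel ``w``, so a constant rate r
    yields AI -> r and AI keeps rate units.  Implemented as a single-pole
    IIR filter (exact discrete exponential), causal.
    """
    psth = np.asarray(psth, dtype=float)
    d = int(round(delta_tc * frame_rate))
    if d > 0:
        psth = np.concatenate([np.zeros(d), psth[:-d] if d < psth.size else []])
    a = np.exp(-1.0 / (tau_i * frame_rate))
    return lfilter([1.0 - a], [1.0, -a], psth)


def sigmoid_inhibition_rate(
    ai: np.ndarray, i0: float, slope: float = 5.0, offset: float = 0.0
) -> np.ndarray:
    """Static sigmoid mapping integrated activity to an inhibition rate:
    ``SI = I0 / (1 + exp(-slope * (AI - O)))``, bounded in [0, I0]."""
    return i0 * expit(slope * (np.asarray(ai, dtype=float) - offset))


def unit_inhibition_rate(
    unit: UnitTrains, duration: float, params: InhibitionParams,
    frame_rate: float = 2000.0,
) -> np.ndarray:
    """SI(t) for one unit, driven by its own trial-averaged ANF rate."""
    counts = bin_unit_trials(unit, duration, "anf", frame_rate)
    psth = counts.mean(axis=0) * frame_rate
    ai = integrate_history(psth, frame_rate, params.delta_tc, params.tau_i)
    return sigmoid_inhibition_rate(ai, params.i0, params.slope, params.offset)


def apply_spontaneous_failures(
    unit: UnitTrains, p_spont_fail: float, seed=None
) -> UnitTrains:
    """Independently relabel each success event as failure with
    probability ``p_spont_fail``; applied before the rate-dependent step."""
    if not 0.0 <= p_spont_fail <= 1.0:
        raise ValueError("p_spont_fail must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = unit.copy()
    for j in range(out.n_trials):
        hit = rng.uniform(size=out.times[j].size) < p_spont_fail
        out.success[j] &= ~hit
    return out


def _deletion_quota(si: np.ndarray, n_trials: int, frame_rate: float,
                    rng: np.random.Generator, rounding: str) -> np.ndarray:
    """Number of events to relabel per bin from the inhibition rate."""
    x = si * n_trials / frame_rate
    if rounding == "stochastic":
        base = np.floor(x)
        return (base + (rng.uniform(size=x.size) < (x - base))).astype(np.int64)
    if rounding == "deterministic":
        return np.round(x).astype(np.int64)
    raise ValueError("rounding must be 'stochastic' or 'deterministic'")


def apply_subtractive_inhibition(
    unit: UnitTrains, si: np.ndarray, frame_rate: float, duration: float,
    seed=None, rounding: str = "stochastic",
) -> UnitTrains:
    """Relabel success events according to an inhibition-rate sequence.

    Per time bin, ``round(SI(t) * n_trials / frame_rate)`` success
    events (stochastic rounding by default) are relabelled failure,
    chosen uniformly at random across the trial pool; if fewer exist,
    all are relabelled.  Event times never change.
    """
    si = np.asarray(si, dtype=float)
    nb = n_bins_for(duration, frame_rate)
    if si.size != nb:
        raise ValueError(
            f"SI length {si.size} does not match the {nb}-bin frame grid"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = unit.copy()
    # flatten all success events with their (trial, index, bin)
    trial_idx, event_idx, bins = [], [], []
    for j in range(out.n_trials):
        mask = out.success[j]
        idx = np.flatnonzero(mask)
        if idx.size:
            trial_idx.append(np.full(idx.size, j))
            event_idx.append(idx)
            bins.append(_bin_indices(out.times[j][idx], frame_rate, nb))
    if not bins:
        return out
    trial_idx = np.concatenate(trial_idx)
    event_idx = np.concatenate(event_idx)
    bins = np.concatenate(bins)
    order = np.argsort(bins, kind="stable")
    trial_idx, event_idx, bins = trial_idx[order], event_idx[order], bins[order]
    quota = _deletion_quota(si, out.n_trials, frame_rate, rng, rounding)
    # group events by bin and relabel a random subset in each
    starts = np.searchsorted(bins, np.arange(nb), side="left")
    ends = np.searchsorted(bins, np.arange(nb), side="right")
    for b in np.flatnonzero(quota):
        lo, hi = starts[b], ends[b]
        avail = hi - lo
        if avail == 0:
            continue
        k = min(int(quota[b]), avail)
        pick = rng.choice(avail, size=k, replace=False) + lo
        for p in pick:
            out.success[trial_idx[p]][event_idx[p]] = False
    return out


def simulate_failure_fraction(
    anf_counts: np.ndarray, si: np.ndarray, p_spont_fail: float,
    frame_rate: float, rng: np.random.Generator, window_bins=None,
    rounding: str = "stochastic",
) -> float:
    """Count-level simulation of the pooled failure fraction.

    Statistically equivalent to relabelling individual events but works
    on per-bin counts only, which makes the per-cell grid search cheap.
    ``anf_counts`` is the trials x bins count matrix of the ANF input.
    """
    n_trials, nb = anf_counts.shape
    total_per_bin = anf_counts.sum(axis=0)
    avail = rng.binomial(total_per_bin, 1.0 - p_spont_fail)
    quota = _deletion_quota(si, n_trials, frame_rate, rng, rounding)
    deleted = np.minimum(quota, avail)
    if window_bins is not None:
        b0, b1 = window_bins
        sl = slice(b0, b1)
    else:
        sl = slice(None)
    n_total = int(total_per_bin[sl].sum())
    if n_total == 0:
        return np.nan
    n_fail = int((total_per_bin[sl] - avail[sl]).sum() + deleted[sl].sum())
    return n_fail / n_total


class SubtractiveInhibition(BaseEstimator):
    """Per-cell subtractive-inhibition model with grid-search fitting.

    ``fit`` selects ``(I0, O)`` by exhaustive grid search so that the
    simulated driven failure fraction matches a target, with the
    spontaneous failure probability set directly to its target;
    ``transform`` relabels the events of a unit accordingly.  The delay,
    integration time constant and sigmoid slope are fixed
    hyperparameters shared across cells.

    Parameters
    ----------
    delta_tc, tau_i, slope : float
        Shared model constants (defaults 0.5 ms, 3 ms, 5).
    i0_grid : int or array-like
        Grid for I0; an int n means ``linspace(0, i0_max, n)``.
    offset_grid : int or array-like
        Grid for O; an int n means n points spanning the observed AI range.
    n_fit_seeds : int
        Simulation repetitions averaged per grid point.
    frame_rate : float
        Time base of the binned PSTH, Hz.
    random_state : int
        Seed for the fitting simulations and for ``transform``.

    Attributes
    ----------
    params_ : InhibitionParams
        The selected parameter set.
    achieved_spont_, achieved_driven_ : float
        Simulated failure fractions at the selected grid point.
    grid_scores_ : ndarray (len(i0_grid), len(offset_grid))
        Mean absolute driven-fraction error per grid point.
    """

    def __init__(self, delta_tc=0.5e-3, tau_i=3e-3, slope=5.0,
                 i0_grid=25, i0_max=300.0, offset_grid=25, n_fit_seeds=3,
                 frame_rate=2000.0, rounding="stochastic", tie_tol=0.002,
                 random_state=0):
        self.delta_tc = delta_tc
        self.tau_i = tau_i
        self.slope = slope
        self.i0_grid = i0_grid
        self.i0_max = i0_max
        self.offset_grid = offset_grid
        self.n_fit_seeds = n_fit_seeds
        self.frame_rate = frame_rate
        self.rounding = rounding
        self.tie_tol = tie_tol
        self.random_state = random_state

    def _grids(self, ai: np.ndarray):
        if np.isscalar(self.i0_grid):
            i0s = np.linspace(0.0, self.i0_max, int(self.i0_grid))
        else:
            i0s = np.asarray(self.i0_grid, dtype=float)
        if np.isscalar(self.offset_grid):
            offs = np.linspace(ai.min(), ai.max(), int(self.offset_grid))
        else:
            offs = np.asarray(self.offset_grid, dtype=float)
        if i0s.size == 0 or offs.size == 0:
            raise ValueError("parameter grids must be nonempty")
        return i0s, offs

    def fit(self, unit: UnitTrains, duration: float,
            target_fail_spont: float = 0.36, target_fail_driven: float = 0.65,
            driven_window=None, spont_window=None):
        """Select (I0, O) matching the observed failure fractions.

        The spontaneous failure probability is set directly to
        ``target_fail_spont``; the grid search minimizes the simulated
        driven-window failure-fraction error, plus the spontaneous-window
        error when a ``spont_window`` is given (so the fitted inhibition
        stays silent at spontaneous rates).  Windows are (start, stop)
        seconds; the driven window defaults to the whole recording.
        """
        for t in (target_fail_spont, target_fail_driven):
            if not 0.0 <= t <= 1.0:
                raise ValueError("failure-fraction targets must lie in [0, 1]")
        counts = bin_unit_trials(unit, duration, "anf", self.frame_rate)
        psth = counts.mean(axis=0) * self.frame_rate
        ai = integrate_history(psth, self.frame_rate, self.delta_tc, self.tau_i)
        i0s, offs = self._grids(ai)

        def win_bins(w):
            if w is None:
                return None
            return (int(round(w[0] * self.frame_rate)),
                    int(round(w[1] * self.frame_rate)))

        dw = win_bins(driven_window)
        sw = win_bins(spont_window)
        ss = np.random.SeedSequence(self.random_state)
        seeds = ss.generate_state(self.n_fit_seeds)
        n_trials = counts.shape[0]
        total_per_bin = counts.sum(axis=0)
        windows = [(slice(*dw) if dw is not None else slice(None),
                    target_fail_driven)]
        if sw is not None:
            # the inhibition must also leave the spontaneous failure
            # fraction at its target, i.e. stay silent at spontaneous rates
            windows.append((slice(*sw), target_fail_spont))
        n_totals = [int(total_per_bin[sl].sum()) for sl, _ in windows]
        if n_totals[0] == 0:
            raise ValueError("no events in the driven window")
        scores = np.zeros((i0s.size, offs.size))
        # common random numbers across grid points: the spontaneous-failure
        # binomial and the stochastic-rounding uniforms are drawn once per
        # simulation seed, which removes between-point simulation noise
        for s in seeds:
            rng = np.random.default_rng(int(s))
            avail = rng.binomial(total_per_bin, 1.0 - target_fail_spont)
            u = rng.uniform(size=ai.size)
            for a, i0 in enumerate(i0s):
                act = i0 * expit(self.slope * (ai - offs[None, :].T))  # (offs, bins)
                x = act * (n_trials / self.frame_rate)
                if self.rounding == "stochastic":
                    base = np.floor(x)
                    quota = base + (u[None, :] < (x - base))
                else:
                    quota = np.round(x)
                deleted = np.minimum(quota, avail[None, :])
                for (sl, target), n_tot in zip(windows, n_totals):
                    if n_tot == 0:
                        continue
                    n_pre_fail = int((total_per_bin[sl] - avail[sl]).sum())
                    frac = (n_pre_fail + deleted[:, sl].sum(axis=1)) / n_tot
                    scores[a] += np.abs(frac - target)
        scores /= len(seeds)
        # plateau-tolerant selection: scores within a sub-resolution margin
        # of the optimum are ties; prefer the least inhibition (smallest I0,
        # then the highest activation threshold)
        tol = self.tie_tol
        cand = np.argwhere(scores <= scores.min() + tol)
        cand = cand[np.lexsort((-cand[:, 1], cand[:, 0]))]
        best = tuple(cand[0])
        self.params_ = InhibitionParams(
            delta_tc=self.delta_tc, tau_i=self.tau_i, slope=self.slope,
            i0=float(i0s[best[0]]), offset=float(offs[best[1]]),
            p_spont_fail=float(target_fail_spont),
        )
        self.grid_scores_ = scores
        self.i0_grid_values_ = i0s
        self.offset_grid_values_ = offs
        # achieved fractions at the chosen point, fresh seeds
        si = sigmoid_inhibition_rate(ai, self.params_.i0, self.slope,
                                     self.params_.offset)
        rng = np.random.default_rng(seeds[0])
        self.achieved_driven_ = float(np.mean([
            simulate_failure_fraction(counts, si, target_fail_spont,
                                      self.frame_rate, rng, dw, self.rounding)
            for _ in range(max(self.n_fit_seeds, 3))
        ]))
        if sw is not None:
            self.achieved_spont_ = float(np.mean([
                simulate_failure_fraction(counts, si, target_fail_spont,
                                          self.frame_rate, rng, sw, self.rounding)
                for _ in range(max(self.n_fit_seeds, 3))
            ]))
        else:
            self.achieved_spont_ = float(target_fail_spont)
        return self

    def transform(self, unit: UnitTrains, duration: float, seed=None) -> UnitTrains:
        """Relabel a unit's events under the fitted parameters."""
        if not hasattr(self, "params_"):
            raise RuntimeError("call fit() before transform()")
        return apply_inhibition(unit, duration, self.params_,
                                frame_rate=self.frame_rate,
                                seed=self.random_state if seed is None else seed,
                                rounding=self.rounding)


def apply_inhibition(
    unit: UnitTrains, duration: float, params: InhibitionParams,
    frame_rate: float = 2000.0, seed=None, rounding: str = "stochastic",
) -> UnitTrains:
    """Full model for one unit: spontaneous failures, then rate-dependent
    spike deletion driven by the unit's own ANF history."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    si = unit_inhibition_rate(unit, duration, params, frame_rate)
    out = apply_spontaneous_failures(unit, params.p_spont_fail, rng)
    return apply_subtractive_inhibition(out, si, frame_rate, duration, rng, rounding)


def fit_cell_params(
    unit: UnitTrains, duration: float, target_fail_spont: float,
    target_fail_driven: float, fixed=(0.5e-3, 3e-3, 5.0), i0_grid=25,
    i0_max=300.0, offset_grid=25, n_fit_seeds=3, frame_rate=2000.0,
    driven_window=None, spont_window=None, seed=0,
) -> InhibitionParams:
    """Functional wrapper over :class:`SubtractiveInhibition` returning
    the fitted :class:`InhibitionParams`."""
    est = SubtractiveInhibition(
        delta_tc=fixed[0], tau_i=fixed[1], slope=fixed[2], i0_grid=i0_grid,
        i0_max=i0_max, offset_grid=offset_grid, n_fit_seeds=n_fit_seeds,
        frame_rate=frame_rate, random_state=seed,
    )
    est.fit(unit, duration, target_fail_spont, target_fail_driven,
            driven_window=driven_window, spont_window=spont_window)
    return est.params_
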