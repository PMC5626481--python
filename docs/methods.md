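# Methods

This note documents the models, parameters and numerical choices behind
`sbcdecode`, and what the synthetic study conditions can and cannot
show.

## Stimulus synthesis

The stimulus emulates a chain of environmental sound textures.  Each
segment is Gaussian noise band-limited by an FFT brick wall to its
carrier band, multiplied by a slow random envelope: standardized
Gaussian noise is low-pass filtered (Gaussian kernel, width =
`modulation_timescale`), exponentiated (log-normal, so the envelope is
positive and right-skewed like natural sound textures), normalized to
its maximum, and mixed toward 1 by the modulation depth,
`env = (1 − depth) + depth · env_norm`.  Depth 0.2 gives a rain-like
steady texture; depth 1.0 a sand-like, fully modulated one.  The
envelope is generated on a 2 kHz grid and linearly interpolated to the
audio rate (97 656.25 Hz); its spectral content lies far below 1 kHz,
so no information is lost.

Adjacent segments overlap during 460 ms transitions in which the
outgoing segment is weighted cos² and the incoming sin² over a phase
running 0→π/2, so the amplitude weights sum to exactly 1 at every
sample.  Total duration is therefore `Σ durations − (n−1)·crossfade`.
The default seven-segment table uses equal durations of ≈ 3.066 s so
the default stimulus is 18.7 s; durations are explicit parameters, so
any other convention can be produced.  The seven default segment
parameter sets (bands within 300–4400 Hz, depths 0.2–1.0, timescales
12–250 ms, level offsets ±2 dB) are stand-ins chosen to span the
rain-to-sand modulation contrast; they are not calibrated fits to any
particular recording.

## ANF population simulation

Each unit has a characteristic frequency (CF); the default population
spaces 32 CFs geometrically over 1.18–3.05 kHz and draws spontaneous
rates from a truncated normal around 71.3 ± 31.8 Hz.  The drive is the
stimulus-spectrogram amplitude envelope near the CF (Gaussian weights
in log-frequency, bandwidth 0.5 octaves), normalized to unit mean over
the driven epoch.  The instantaneous rate is

    rate(t) = spont_rate + driven_gain · env_norm(t)^exponent

with `driven_gain = 58.4` Hz (so the mean driven rate lands near the
130 Hz regime of ANFs under natural sounds) and a linear nonlinearity
(`exponent = 1`) as the simplest model producing that regime.  Spikes
are drawn by thinning a homogeneous Poisson process at the peak rate —
exact and simple to test — and a 0.7 ms dead time then enforces
refractoriness.  The dead time biases realized rates a few percent
below nominal (≈ 9% at 130 Hz); the defaults accept this bias rather
than pre-compensating it.  A spontaneous epoch is realized by
prepending 2 s of floor-level frames to the spectrogram before
simulation; reconstruction and evaluation use the driven epoch only.

What the generator does **not** emulate: cochlear filter cascades,
adaptation, phase locking to the carrier fine structure, synaptic
depression, or correlated noise across fibers.  Passing tests therefore
show that the analysis chain behaves correctly on Poisson-like,
envelope-driven inputs with realistic rates and tuning — not that it
reproduces in vivo values, which depend on the recorded data.

## Spike-train statistics

All statistics share one time base: 0.5 ms bins (2 kHz), the same frame
rate as the spectrogram, with half-open bin intervals.  Sparsity is
computed from the trial-averaged rate; the raw formula
`1 − ⟨r⟩²/⟨r²⟩` is the default, and an optional flag divides by
`1 − 1/N` so the upper bound is exactly 1 for any bin count (both modes
exist because published values rarely state which convention was
used).  Reproducibility excludes trial pairs containing an empty trial
(their normalization is 0/0) and reduces the pair count accordingly,
with a warning.  The full correlogram is available but only the lag-0
value enters the statistic, so no zero-padding bias correction is
applied at nonzero lags.

## Subtractive inhibition

The model relabels events only — spike times are never moved or
created, so the ANF stream is identical before and after, and the SBC
stream is a subset.  Stages, in order:

1. **Spontaneous failures**: each success event is independently
   relabelled with probability `p_spont_fail`.
2. **Rate-dependent deletion**: the unit's own trial-averaged ANF rate
   is delayed by Δt_c = 0.5 ms and filtered with a unit-area
   exponential kernel (τ_I = 3 ms), implemented as a single-pole IIR
   filter — the exact discrete exponential.  The unit-area convention
   makes AI(t) a smoothed rate in Hz, so the sigmoid offset O is
   interpretable in Hz; the alternative (unnormalized) convention only
   rescales O and the slope.  The sigmoid `SI = I₀/(1 + e^{−S(AI−O)})`
   with S = 5 (units 1/Hz) is nearly a threshold on AI.  Per bin,
   `SI·n_trials/frame_rate` events are relabelled; the fractional part
   is resolved by stochastic rounding (floor plus a Bernoulli draw) so
   expected deletions are exact, with deterministic rounding available
   by flag.  Deleted events are chosen uniformly across the pooled
   trials of the bin; if the quota exceeds the available successes, the
   bin is emptied.

Driving AI from the unit's own history is a choice: pooling across
similarly tuned fibers would also be defensible, but single-unit
history keeps units independent and is the minimal reading of
"recent activity in this CF range".

**Fitting.** `p_spont_fail` is set directly to the spontaneous target;
(I₀, O) are selected by exhaustive grid search (default 25 I₀ values
over 0–300 Hz × 25 O values spanning the observed AI range).  The
objective is the seed-averaged absolute error of the simulated driven
failure fraction, plus the spontaneous-window error when a spontaneous
epoch exists — without the second term the search happily picks
parameter sets that also crush spontaneous activity.  The simulation
inside the objective works on per-bin counts (binomial spontaneous
failures, quota-clamped deletions), which is distributionally identical
to event-level relabelling for the pooled fraction but orders of
magnitude faster; common random numbers across grid points remove
between-point simulation noise.  Because spikes are discrete the error
surface has plateaus: grid points within `tie_tol = 0.002` (below the
count resolution of the data) of the optimum are treated as ties and
the least-inhibition point (smallest I₀, then highest O) is selected.

## Spectrogram and decoder

Spectrogram frames of 512 samples start at `round(i·SR/2000)`, so the
2 kHz frame grid is shared with the binned responses and neighbouring
frames overlap heavily.  A Hann window is the default (rectangular is
available); power is `|FFT|²` in dB (10·log10), clipped 60 dB below the
maximum so silence stays finite.  Reconstruction is restricted to
300–4400 Hz (22 bands) and is computed on dB values.

The decoder solves, per band, the ridge normal equation on a lagged
design (response lags 0–25 ms after the stimulus frame, covering
response latencies and the ~10 ms inhibitory timescale; out-of-range
lags zero-padded).  Features are centered and scaled to unit variance
and the Gram matrix divided by the number of time bins, so λ = 0.1 is
applied relative to a unit-diagonal response correlation matrix and is
scale-free; zero-variance features get scale 1 and carry zero weight.
Per-band target means are the intercepts, re-added on prediction.
Cross-validation uses contiguous equal time blocks (default 10); each
fold's Gram and cross-moment matrices are assembled by subtracting the
held-out section's moments from the precomputed totals, with exact
per-fold re-centering of features and targets.  Feature scales are
taken from the full recording (a per-fold rescaling changes solutions
only through the ridge term).  Reported summary values average the
cross-validated section means with the in-sample estimate.

## Evaluation

- **Correlation decomposition**: overall Pearson over all (t, f) cells;
  temporal = per-band correlation over time, averaged; spectral =
  per-time-bin correlation across bands, averaged; zero-variance
  bands/bins excluded.  `variance_db` is the standard deviation of the
  reconstructed dB values (a spread in dB; the raw variance is its
  square — the literature is ambiguous about which is meant, and the SD
  has dB units).
- **CLD**: joint (real, reconstructed) level histogram in 1 dB bins on
  shared edges, each real-level column normalized to sum 1; empty
  columns stay zero and are flagged.  Differences of two CLDs cancel
  columnwise wherever both are populated.  Slopes come from OLS of
  reconstructed on real levels with a t-based 95% CI.
- **Autocorrelation width**: per band, the mean-subtracted temporal
  autocorrelation normalized at lag 0; the width at relative height h
  is the full span between the first crossings of h, linearly
  interpolated between lag samples; default maximum lag 100 ms
  (slowly modulated reconstructions may not cross low heights within
  it — such heights are NaN with a warning, and analyses that need the
  crossing can extend `autocorr_max_lag`).
- **Modulation spectrum**: Welch PSD of each band's mean-subtracted dB
  time course, averaged over bands, with the integral over a
  modulation band (default 100–150 Hz) reported.
- **Spectral correlation**: zero-lag (same-time-bin) Pearson
  correlation over time between band pairs, averaged per frequency
  separation; exactly 1 at separation 0; constant bands excluded.
- **Cohen's U1**: the fraction of pooled observations outside the
  overlap of the two groups' ranges.

## Study conditions and problem sizes

The package's default conditions are the regime described above
(18.7 s stimulus, 32 units, 20 trials, 2 s spontaneous epoch,
failure-fraction targets 0.36/0.65).  The end-to-end test battery runs
a scaled-down population — 16 units, 10 trials, five generator seeds —
and asserts the directional consequences of inhibition as inequalities
of seed means: lower overall reconstruction correlation and dB spread
for the SBC stream, narrower autocorrelation at heights ≥ 0.5, and
higher across-frequency correlation at large separations.  Those
inequalities mirror the qualitative physiology; the in vivo magnitudes
themselves are properties of the recorded data and are out of scope.

## Known limitations

- Inhibition is driven by the same-unit PSTH; cross-CF pooling of
  inhibitory drive is not modelled.
- The decoder is linear and phase-blind: only envelope fine structure
  can be reconstructed, never carrier fine structure.
- The grid-search fit matches pooled failure fractions, not the full
  temporal pattern of failures.
- WAV files store an integer header rate; the exact fractional rate
  travels in a JSON sidecar which takes precedence on read.
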