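# sbcdecode

Spherical bushy cells (SBCs) in the anteroventral cochlear nucleus
receive giant auditory-nerve-fiber (ANF) synapses — the endbulbs of
Held — whose every presynaptic event can be recorded and labelled by
whether it triggered a postsynaptic spike.  Acoustically evoked
inhibition deletes a large share of these events, and the deletions are
activity-dependent: the stronger the recent ANF drive, the more spikes
are removed.  This gain control makes the SBC output sparser and more
reproducible across trials, but it also compresses the neural
representation of sound level.

`sbcdecode` is a tested pipeline for quantifying that trade-off on
synthetic data.  It provides:

- **a stimulus/population generator** — a segmented, amplitude-modulated
  noise stimulus (seven environmental-sound-like textures joined by
  cos² crossfades, 18.7 s total) and an inhomogeneous-Poisson ANF
  population (default 32 units, CFs 1.18–3.05 kHz, spontaneous rates
  ≈ 71 Hz) driven by the stimulus envelope at each unit's characteristic
  frequency;
- **spike-train statistics** — firing rates, failure fractions, the
  variance-based sparsity `S = 1 − ⟨r(t)⟩²_t / ⟨r(t)²⟩_t`, and the
  across-trial reproducibility (pair-averaged lag-0 cross-correlation
  normalized by `S₁S₂/N_bins`, minus 1; 0 for fixed-rate Poisson);
- **a subtractive-inhibition model** (`SubtractiveInhibition`, a
  scikit-learn-style estimator) — the ANF rate is delayed by
  Δt_c = 0.5 ms, integrated with a τ_I = 3 ms exponential kernel into
  AI(t), passed through the sigmoid `SI(t) = I₀ / (1 + e^{−S(AI−O)})`
  (S = 5), and `SI(t)·n_trials/frame_rate` spikes per 0.5 ms bin are
  relabelled as failures, chosen randomly across trials.  `fit` selects
  (I₀, O) per cell by exhaustive grid search so the simulated failure
  fractions match targets (defaults 0.36 spontaneous / 0.65 driven);
- **a linear stimulus decoder** (`SpectrogramDecoder`, scikit-learn
  estimator) — per frequency band f, kernels g_f(τ, n) over response
  lags τ and units n solve the ridge-regularized normal equation
  `g_f = (C_RR + λI)⁻¹ C_RS_f` with λ = 0.1, reconstructing the
  stimulus spectrogram (2 kHz frame rate, 512-sample windows, 300–4400
  Hz band) as `Ŝ(t,f) = Σ_τ Σ_n g_f(τ,n) R(t+τ,n)`, with 10-section
  cross-validation averaged with the in-sample estimate;
- **reconstruction diagnostics** — overall/temporal/spectral correlation
  decomposition, conditional level densities (CLDs) and their slopes
  and differences, autocorrelation widths at relative heights, temporal
  modulation spectra (100–150 Hz band), across-frequency correlations,
  and Cohen's U1.

## Worked example

```python
import numpy as np
from sbcdecode import RunConfig, failure_fraction, firing_rate
from sbcdecode.pipeline import simulate_experiment, analyze_stream

cfg = RunConfig(seed=5, n_units=16, n_trials=10, autocorr_max_lag=1.0)
exp = simulate_experiment(cfg)   # synth + simulate + fit/apply inhibition

print(f"ANF rate  spont/driven: {firing_rate(exp.events, 'anf', exp.spont_window).mean():5.1f} / "
      f"{firing_rate(exp.events, 'anf', exp.driven_window).mean():5.1f} Hz")
print(f"SBC rate  spont/driven: {firing_rate(exp.events, 'sbc', exp.spont_window).mean():5.1f} / "
      f"{firing_rate(exp.events, 'sbc', exp.driven_window).mean():5.1f} Hz")
print(f"failure fraction spont/driven: "
      f"{failure_fraction(exp.events, exp.spont_window).mean():.2f} / "
      f"{failure_fraction(exp.events, exp.driven_window).mean():.2f}")
for stream in ("anf", "sbc"):
    r = analyze_stream(exp, stream)
    s = r["report"].summary
    print(f"{stream.upper():4s} corr={s['correlation_overall']:.2f}  "
          f"sd={s['variance_db']:.1f} dB  "
          f"width@0.5={r['autocorr_widths'][1]*1e3:.0f} ms  "
          f"CLD slope={r['cld_slope']:.2f}")
```

Output:

```
ANF rate  spont/driven:  71.0 / 118.0 Hz
SBC rate  spont/driven:  41.8 /  41.9 Hz
failure fraction spont/driven: 0.41 / 0.64
ANF  corr=0.68  sd=12.8 dB  width@0.5=1494 ms  CLD slope=0.54
SBC  corr=0.47  sd=10.1 dB  width@0.5=36 ms  CLD slope=0.24
```

Reading the numbers: the fitted inhibition holds the SBC output rate
during stimulation at its spontaneous level (41.9 vs 41.8 Hz) even
though the ANF input rate rises from 71 to 118 Hz — the failure
fraction climbs from 0.41 to 0.64.  Decoding the stimulus spectrogram
from the population shows the cost and the benefit: the SBC-based
reconstruction matches the stimulus less well overall (correlation 0.47
vs 0.68) and spans a smaller dynamic range (10.1 vs 12.8 dB spread;
CLD slope 0.24 vs 0.54, i.e. a compressed level mapping), but it is
temporally much sharper (autocorrelation half-height width 36 ms vs
1.5 s).

A full run that writes WAV/HDF5/CSV/JSON artifacts:

```bash
sbcdecode run --seed 1 --out results/run1
```

See `docs/methods.md` for model details, parameter meanings, and known
limitations.

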