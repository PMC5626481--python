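"""Run configuration: defaults, YAML loading, and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml


@dataclass
class RunConfig:
    """Resolved parameters for a full pipeline run.

    The defaults are the package's study conditions: a seven-segment
    18.7 s stimulus at 97656.25 Hz, 32 units with CFs in 1.18-3.05 kHz,
    20 trials, spectrogram/response frame rate 2 kHz with 512-sample
    windows restricted to 300-4400 Hz, ridge weight 0.1, response lags
    0-25 ms, 10 cross-validation sections, failure-fraction targets
    0.36 (spontaneous) / 0.65 (driven).
    """

    seed: int = 0
    sample_rate: float = 97656.25
    crossfade: float = 0.46
    segments: list = None  # None -> default seven-segment table
    n_units: int = 32
    n_trials: int = 20
    spont_pad: float = 2.0  # leading silence, s (spontaneous window)
    frame_rate: float = 2000.0
    window_samples: int = 512
    band: tuple = (300.0, 4400.0)
    ridge_lambda: float = 0.1
    lag_window: tuple = (0.0, 0.025)
    n_sections: int = 10
    target_fail_spont: float = 0.36
    target_fail_driven: float = 0.65
    i0_grid: int = 25
    i0_max: float = 300.0
    offset_grid: int = 25
    n_fit_seeds: int = 3
    cld_bin_width: float = 1.0
    relative_heights: tuple = (0.3, 0.5, 0.7, 0.9)
    autocorr_max_lag: float = 0.1
    modulation_band: tuple = (100.0, 150.0)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg
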