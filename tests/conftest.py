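import pytest

import sbcdecode as sd


@pytest.fixture(scope="session")
def short_wave():
    """A 2-segment, ~2.8 s stimulus for spectrogram/pipeline tests."""
    segs = [
        sd.SegmentSpec(1.5, 300, 4400, 0.3, 0.05, 0.0, "broad"),
        sd.SegmentSpec(1.5, 800, 3500, 0.9, 0.02, 0.0, "rough"),
    ]
    return sd.synthesize_stimulus(segs, crossfade=0.2, seed=7), segs


@pytest.fixture(scope="session")
def small_events():
    """A tiny hand-built event set: 2 units, 3 trials, 2 s."""
    u0 = sd.UnitTrains(
        cf=1500.0,
        times=[[0.1, 0.5, 1.2], [0.3, 0.9], [0.2, 0.6, 1.5, 1.9]],
        success=[[True, False, True], [True, True], [False, True, True, False]],
    )
    u1 = sd.UnitTrains(
        cf=2500.0,
        times=[[0.05, 1.0], [0.4], []],
        success=[[True, True], [False], []],
    )
    return sd.EventTrainSet([u0, u1], duration=2.0)
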