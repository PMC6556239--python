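import numpy as np
import pytest

from pulsetrack import (PipelineConfig, make_windowed_hr, run_pipeline,
                        standard_fixtures)


@pytest.fixture(scope="session")
def fixtures():
    """Canonical synthetic test set, generated once per session."""
    return standard_fixtures()


@pytest.fixture(scope="session")
def heavy_results(fixtures):
    """Full pipeline vs no-MA ablation on the heavy-artifact fixture."""
    frame, truth = fixtures["heavy_artifact"]
    hr_full = run_pipeline(frame)
    cfg_ablation = PipelineConfig.from_dict(
        {"ma": {"algorithm": "none"}, "anf": {"feedback": False}})
    hr_ablation = run_pipeline(frame, cfg_ablation)
    truth_w = make_windowed_hr(truth.per_sample, frame.fs)
    return {"frame": frame, "truth": truth, "truth_w": truth_w,
            "hr_full": hr_full, "hr_ablation": hr_ablation}


def fft_peak_hz(x, fs):
    """Frequency of the global magnitude peak of a windowed FFT."""
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x))))
    return np.fft.rfftfreq(len(x), 1.0 / fs)[int(np.argmax(spec))]


def band_power(x, fs, f0, half_width=0.15):
    """Total spectral power within f0 ± half_width Hz."""
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    mask = (freqs > f0 - half_width) & (freqs < f0 + half_width)
    return float(spec[mask].sum())
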