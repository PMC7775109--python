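import numpy as np
import pytest

import wordrhythm as wr


@pytest.fixture(scope="session")
def metrical_iso():
    """Small metrical isochronous timeline (~20 sentences, ~8 trials)."""
    return wr.assign_isochronous_timing(
        wr.generate_metrical_timeline(280, seed=7))


@pytest.fixture(scope="session")
def nonmetrical_iso():
    return wr.assign_isochronous_timing(
        wr.generate_nonmetrical_timeline(280, seed=8))


def clean_config(fs=128.0, **kw):
    """Noise-free fast-mode simulation config."""
    base = dict(sampling_rate=fs, amplitude_word=1.0, amplitude_syllable=0.0,
                amplitude_am=0.0, noise_sd=0.0, eog_gain=0.0, eog_sd=0.0,
                artifact_rate=0.0, seed=0)
    base.update(kw)
    return wr.SimulationConfig(**base)


@pytest.fixture(scope="session")
def amplified_pair(metrical_iso):
    s1 = wr.apply_amplitude_condition(metrical_iso, "sigma1_amplified")
    s2 = wr.apply_amplitude_condition(metrical_iso, "sigma2_amplified")
    return s1, s2


def analyze_clean(timeline, cfg, filter_chain=True):
    """Noise-free simulation → (optionally band-passed) epochs → spectrum."""
    from wordrhythm import preprocess as pp
    rec = wr.simulate_recording(timeline, cfg)
    if filter_chain:
        rec = pp.rereference_mastoids(rec)
        spec = pp.design_bandpass_fir(rec.sampling_rate)
        rec = pp.apply_filter_compensated(rec, spec)
    epochs = pp.segment_trials(rec, timeline)
    return wr.average_and_spectrum(epochs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
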