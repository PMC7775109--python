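"""Forward simulation of multichannel EEG with word-, syllable- and AM-locked components.

The response model is linear: each component is an evoked-response kernel
(support within 0–0.75 s of the eliciting event) convolved with the
component's event impulse train, scaled, and spread over the scalp by a
per-channel topography with maximum weight 1.  Background activity is
1/f^alpha Gaussian noise; ocular activity is a low-frequency random walk
recorded on the EOG channels and leaked into frontal EEG channels, which
gives the EOG-regression stage something real to remove.

64 scalp channels (10-10 names, BioSemi layout) plus HEOG, VEOG and the
two mastoids M1/M2 are simulated at 2048 Hz by default; a 128-Hz fast
mode is available for analyses that start at the downsampled rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .stimulus import SyllableTimeline

__all__ = [
    "EEG_CHANNELS", "AUX_CHANNELS", "EEGRecording", "SimulationConfig",
    "make_erp_kernel", "named_topography", "simulate_recording",
    "simulate_experiment", "oneoverf_noise",
]

#: kernel support, s — every evoked kernel must vanish outside [0, KERNEL_SPAN]
KERNEL_SPAN = 0.75

# 64-channel BioSemi montage in standard 10-10 names (A1..B32 order)
EEG_CHANNELS = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]
AUX_CHANNELS = ["HEOG", "VEOG", "M1", "M2"]

_CENTRO_FRONTAL = {
    "FCz": 1.0, "Cz": 0.95, "Fz": 0.9, "FC1": 0.85, "FC2": 0.85, "C1": 0.8,
    "C2": 0.8, "F1": 0.7, "F2": 0.7, "FC3": 0.65, "FC4": 0.65, "CPz": 0.6,
    "C3": 0.5, "C4": 0.5, "F3": 0.45, "F4": 0.45, "AFz": 0.4, "CP1": 0.4,
    "CP2": 0.4,
}
_TEMPORAL = {
    "T7": 1.0, "T8": 1.0, "TP7": 0.85, "TP8": 0.85, "FT7": 0.8, "FT8": 0.8,
    "C5": 0.7, "C6": 0.7, "CP5": 0.55, "CP6": 0.55, "FC5": 0.5, "FC6": 0.5,
    "P7": 0.4, "P8": 0.4,
}
_FRONTAL_EOG_LEAK = {
    "Fp1": 1.0, "Fp2": 1.0, "Fpz": 1.0, "AF7": 0.8, "AF8": 0.8, "AF3": 0.7,
    "AF4": 0.7, "AFz": 0.7, "F7": 0.45, "F8": 0.45, "F5": 0.35, "F6": 0.35,
    "F3": 0.3, "F4": 0.3, "F1": 0.25, "F2": 0.25, "Fz": 0.25,
}


def named_topography(kind: str, baseline: float = 0.15) -> np.ndarray:
    """Per-EEG-channel weight map with max weight 1.

    ``kind`` is ``centro_frontal`` (word and syllable responses),
    ``temporal`` (AM response; the word/AM topography contrast is largest
    over temporal electrodes) or ``eog_leak`` (frontal ocular leakage,
    baseline 0 elsewhere).
    """
    if kind == "centro_frontal":
        table, base = _CENTRO_FRONTAL, baseline
    elif kind == "temporal":
        table, base = _TEMPORAL, baseline
    elif kind == "eog_leak":
        table, base = _FRONTAL_EOG_LEAK, 0.0
    else:
        raise ValueError(f"unknown topography kind {kind!r}")
    return np.array([table.get(ch, base) for ch in EEG_CHANNELS])


@dataclass
class EEGRecording:
    """Multichannel time series in µV with channel roles encoded in the labels."""

    data: np.ndarray                      # channels × samples
    sampling_rate: float
    channel_labels: list[str]
    reference_state: str = "raw"          # 'raw' or 'mastoid_avg'
    processing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("data rows must match channel_labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def eeg_indices(self) -> np.ndarray:
        aux = set(AUX_CHANNELS)
        return np.array([i for i, ch in enumerate(self.channel_labels)
                         if ch not in aux])

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.sampling_rate,
                            list(self.channel_labels), self.reference_state,
                            list(self.processing))


def make_erp_kernel(shape: str, latency: float, width: float,
                    polarity: int = 1, sampling_rate: float = 128.0) -> np.ndarray:
    """Sample a unit-peak evoked-response kernel on [0, 0.75) s.

    ``gamma`` gives a single smooth lobe with its mode at ``latency`` and
    spread ``width`` (standard deviation ≈ width/2); ``windowed_sine``
    gives a half-sine lobe occupying [latency, latency + width].
    """
    if latency < 0 or width < 0:
        raise ValueError("latency and width must be non-negative")
    if latency + width > KERNEL_SPAN:
        raise ValueError(
            f"kernel support [{latency}, {latency + width}] exceeds "
            f"{KERNEL_SPAN} s")
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    n = int(round(KERNEL_SPAN * sampling_rate))
    t = np.arange(n) / sampling_rate
    if width < 1.0 / sampling_rate:     # impulse limit
        k = np.zeros(n)
        k[int(round(latency * sampling_rate))] = 1.0
        return polarity * k
    if shape == "gamma":
        target = width / (2.0 * max(latency, 1e-6))

        def mode_over_sd(a):            # (a-1)*theta is the mode, sqrt(a)*theta the sd
            return np.sqrt(a) / (a - 1.0)
        a = brentq(lambda a: mode_over_sd(a) - target, 1.0 + 1e-9, 1e7)
        theta = latency / (a - 1.0)
        k = gamma_dist.pdf(t, a, scale=theta)
        # smooth fade over the last 50 ms guarantees zero support past 0.75 s
        n_fade = int(round(0.05 * sampling_rate))
        if n_fade > 1:
            k[-n_fade:] *= 0.5 * (1 + np.cos(np.pi * np.arange(n_fade) / n_fade))
        k /= k.max()
    elif shape == "windowed_sine":
        k = np.zeros(n)
        inside = (t >= latency) & (t < latency + width)
        k[inside] = np.sin(np.pi * (t[inside] - latency) / width)
        if k.max() > 0:
            k /= k.max()
    else:
        raise ValueError(f"unknown kernel shape {shape!r}")
    return polarity * k


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the forward model.

    Amplitudes are in µV (kernel peaks are 1 before scaling); topographies
    are per-EEG-channel weights with max 1.  ``noise_exponent`` is the
    spectral slope alpha of the 1/f^alpha background; ``eog_gain`` scales
    the frontal leakage of the ocular component into the EEG channels.
    """

    sampling_rate: float = 2048.0
    amplitude_word: float = 1.0
    amplitude_syllable: float = 1.0
    amplitude_am: float = 1.0
    kernel_word: np.ndarray | None = None
    kernel_syllable: np.ndarray | None = None
    kernel_am: np.ndarray | None = None
    topography_word: np.ndarray | None = None
    topography_syllable: np.ndarray | None = None
    topography_am: np.ndarray | None = None
    noise_exponent: float = 1.0
    noise_sd: float = 0.0
    eog_gain: float = 0.0
    eog_sd: float = 50.0
    artifact_rate: float = 0.0        # occasional large transients, events/s
    pad_after: float = 4.0            # tail margin after the last offset, s
    seed: int | None = None

    def __post_init__(self) -> None:
        fs = self.sampling_rate
        if self.kernel_word is None:
            self.kernel_word = make_erp_kernel("gamma", 0.20, 0.25, +1, fs)
        if self.kernel_syllable is None:
            self.kernel_syllable = make_erp_kernel("gamma", 0.11, 0.12, +1, fs)
        if self.kernel_am is None:
            self.kernel_am = make_erp_kernel("gamma", 0.14, 0.16, +1, fs)
        if self.topography_word is None:
            self.topography_word = named_topography("centro_frontal")
        if self.topography_syllable is None:
            self.topography_syllable = named_topography("centro_frontal")
        if self.topography_am is None:
            self.topography_am = named_topography("temporal")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("kernel_word", "kernel_syllable", "kernel_am"):
            k = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(k)):
                raise ValueError(f"{name} must be finite")
            if len(k) > int(round(KERNEL_SPAN * fs)):
                raise ValueError(f"{name} support exceeds {KERNEL_SPAN} s")
            setattr(self, name, k)


def oneoverf_noise(rng: np.random.Generator, shape: tuple, sampling_rate: float,
                   exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f^exponent, per-row sd fixed."""
    from scipy.fft import irfft, next_fast_len
    n = shape[-1]
    n_fast = next_fast_len(n)           # pad: FFTs at awkward lengths are slow
    n_bins = n_fast // 2 + 1
    # draw the spectrum directly (single inverse FFT, single-precision noise)
    spec = (rng.standard_normal(shape[:-1] + (n_bins,), dtype=np.float32)
            + 1j * rng.standard_normal(shape[:-1] + (n_bins,), dtype=np.float32))
    f = np.fft.rfftfreq(n_fast, 1.0 / sampling_rate).astype(np.float32)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** np.float32(-exponent / 2.0)
    scale[0] = 0.0
    out = irfft(spec * scale, n=n_fast, axis=-1)[..., :n].astype(float)
    rms = out.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return sd * out / rms


def _component(train_onsets: np.ndarray, kernel: np.ndarray, n: int,
               fs: float) -> np.ndarray:
    train = np.zeros(n)
    idx = np.round(train_onsets * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    train[idx] = 1.0
    return fftconvolve(train, kernel)[:n]


def simulate_recording(timeline: SyllableTimeline,
                       config: SimulationConfig) -> EEGRecording:
    """Simulate one continuous recording for one participant and condition.

    data = Σ_component amplitude · topography ⊗ (kernel ⊛ impulse train)
           + 1/f^alpha noise + eog_gain · ocular leakage.
    Deterministic given ``config.seed``.
    """
    if not timeline.has_timing:
        raise ValueError("timeline needs assigned timing before simulation")
    fs = config.sampling_rate
    n = int(round((timeline.span + config.pad_after) * fs))
    if n < int(round(timeline.span * fs)):
        raise ValueError("recording shorter than the timeline span")
    labels = EEG_CHANNELS + AUX_CHANNELS
    data = np.zeros((len(labels), n))
    n_eeg = len(EEG_CHANNELS)

    comps = [
        (timeline.onsets[timeline.word_onset], config.kernel_word,
         config.amplitude_word, config.topography_word),
        (timeline.onsets, config.kernel_syllable,
         config.amplitude_syllable, config.topography_syllable),
        (timeline.onsets[timeline.amplified], config.kernel_am,
         config.amplitude_am, config.topography_am),
    ]
    for onsets, kernel, amp, topo in comps:
        if amp == 0 or len(onsets) == 0:
            continue
        sig = _component(onsets, np.asarray(kernel), n, fs)
        data[:n_eeg] += amp * np.asarray(topo)[:, None] * sig[None, :]

    rng = np.random.default_rng(config.seed)
    if config.eog_gain or config.eog_sd:
        # ocular component: integrated white noise, linear drift removed
        from scipy.signal import detrend
        walk = detrend(np.cumsum(rng.standard_normal((2, n)), axis=-1), axis=-1)
        sd = walk.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        walk = config.eog_sd * walk / sd
        heog, veog = walk
        data[labels.index("HEOG")] += heog
        data[labels.index("VEOG")] += veog
        if config.eog_gain:
            leak = named_topography("eog_leak")
            data[:n_eeg] += config.eog_gain * leak[:, None] * veog[None, :]
    if config.noise_sd > 0:
        data += oneoverf_noise(rng, (len(labels), n), fs,
                               config.noise_exponent, config.noise_sd)
    if config.artifact_rate > 0:
        # occasional large transients (movement/electrode pops): Hann bursts
        # of 300-800 µV on a few channels, Poisson-spread over the recording
        n_events = rng.poisson(config.artifact_rate * n / fs)
        for _ in range(n_events):
            start = int(rng.integers(0, n))
            dur = int(rng.uniform(0.15, 0.40) * fs)
            stop = min(start + dur, n)
            burst = (rng.uniform(300, 800) * rng.choice([-1, 1])
                     * np.hanning(dur)[: stop - start])
            chans = rng.choice(n_eeg, size=int(rng.integers(1, 5)), replace=False)
            data[chans, start:stop] += burst[None, :]

    return EEGRecording(data, fs, labels, reference_state="raw",
                        processing=["simulate"])


def _shift_kernel(kernel: np.ndarray, shift_samples: int) -> np.ndarray:
    """Latency-shift a kernel with zero fill (no wrap-around)."""
    out = np.zeros_like(kernel)
    if shift_samples >= 0:
        out[shift_samples:] = kernel[:len(kernel) - shift_samples]
    else:
        out[:shift_samples] = kernel[-shift_samples:]
    return out


@dataclass
class ParticipantDraw:
    """Between-subject ground truth actually used for one participant."""

    amplitude_scale: float
    latency_shift: float      # s, applied to all kernels
    seed: int


def simulate_experiment(n_participants: int, conditions: dict,
                        config: SimulationConfig, master_seed: int = 0,
                        amplitude_sigma: float = 0.0,
                        latency_sd: float = 0.0):
    """Simulate ``n_participants`` × ``conditions`` recordings.

    ``conditions`` maps a condition name to its :class:`SyllableTimeline`.
    Per-participant amplitude scaling is log-normal with log-sd
    ``amplitude_sigma``; latency jitter is Gaussian with sd ``latency_sd``
    seconds (kernels are shifted by whole samples).  All seeds derive
    deterministically from ``master_seed``.

    Returns ``(recordings, draws)``: ``recordings[(participant, condition)]``
    and the per-participant :class:`ParticipantDraw` ground truth.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    root = np.random.default_rng(master_seed)
    fs = config.sampling_rate
    recordings = {}
    draws = []
    for p in range(n_participants):
        scale = float(np.exp(amplitude_sigma * root.standard_normal())) \
            if amplitude_sigma else 1.0
        shift = float(latency_sd * root.standard_normal()) if latency_sd else 0.0
        shift_samp = int(round(shift * fs))
        draw = ParticipantDraw(scale, shift_samp / fs,
                               int(root.integers(0, 2 ** 31 - 1024)))
        draws.append(draw)
        for c, (name, tl) in enumerate(conditions.items()):
            cfg = SimulationConfig(
                sampling_rate=fs,
                amplitude_word=config.amplitude_word * scale,
                amplitude_syllable=config.amplitude_syllable * scale,
                amplitude_am=config.amplitude_am * scale,
                kernel_word=_shift_kernel(config.kernel_word, shift_samp),
                kernel_syllable=_shift_kernel(config.kernel_syllable, shift_samp),
                kernel_am=_shift_kernel(config.kernel_am, shift_samp),
                topography_word=config.topography_word,
                topography_syllable=config.topography_syllable,
                topography_am=config.topography_am,
                noise_exponent=config.noise_exponent,
                noise_sd=config.noise_sd,
                eog_gain=config.eog_gain,
                eog_sd=config.eog_sd,
                artifact_rate=config.artifact_rate,
                pad_after=config.pad_after,
                seed=draw.seed + c,
            )
            recordings[(p, name)] = simulate_recording(tl, cfg)
    return recordings, draws
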