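"""Separation of word-locked and AM-locked response components, and ERPs.

In the σ1-amplified condition the amplified syllables coincide with word
onsets; in the σ2-amplified condition they lag by 250 ms.  At 2 Hz a
250-ms lag is half a cycle, so:

* averaging the two condition responses as-is preserves the word-locked
  component and cancels the AM-locked one (``word_average``);
* delaying the σ1-amplified response by 250 ms before averaging aligns
  the AM and cancels the word-locked component (``am_average``).

The delay is applied circularly within each 7-s trial: trials are
phase-continuous and 7 s is an integer number of 0.5-s word periods, so
the wrap preserves exact 2-Hz antiphase cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedResponse
from .simulate import EEGRecording
from .stimulus import SyllableTimeline

__all__ = ["ERPPair", "word_average", "am_average", "normalize_topography",
           "disyllabic_erps"]

AM_DELAY = 0.25          # σ1-condition realignment delay, s
BASELINE_WINDOW = 0.10   # pre-onset baseline, s
ERP_SPAN = 0.75          # post-onset ERP window, s


def _pair_arrays(a, b):
    da = a.data if isinstance(a, EpochedResponse) else np.asarray(a, dtype=float)
    db = b.data if isinstance(b, EpochedResponse) else np.asarray(b, dtype=float)
    if da.shape != db.shape:
        raise ValueError(f"condition responses differ in shape: {da.shape} vs {db.shape}")
    return da, db


def _like(template, data):
    if isinstance(template, EpochedResponse):
        return EpochedResponse(data, template.sampling_rate,
                               list(template.channel_labels),
                               template.epoch_duration,
                               processing=list(template.processing))
    return data


def word_average(resp_sigma1, resp_sigma2):
    """Elementwise mean of the σ1- and σ2-amplified responses.

    Word onsets are aligned across the two conditions, so the word-locked
    component is preserved; the AM-locked 2-Hz component is 180° out of
    phase between conditions and cancels.
    """
    a, b = _pair_arrays(resp_sigma1, resp_sigma2)
    return _like(resp_sigma1, 0.5 * (a + b))


def am_average(resp_sigma1, resp_sigma2, delay: float = AM_DELAY,
               sampling_rate: float | None = None):
    """Mean after delaying the σ1-amplified response by 250 ms.

    The delay realigns the amplified syllables across conditions, so the
    AM-locked component is preserved while the word-locked 2-Hz component
    cancels.  The shift must be an integer number of samples (32 at
    128 Hz); it is applied circularly along the last (time) axis.  With
    ``delay=0`` this degenerates to :func:`word_average`.
    """
    a, b = _pair_arrays(resp_sigma1, resp_sigma2)
    fs = sampling_rate
    if fs is None:
        if not isinstance(resp_sigma1, EpochedResponse):
            raise ValueError("pass sampling_rate when using bare arrays")
        fs = resp_sigma1.sampling_rate
    shift_f = delay * fs
    shift = int(round(shift_f))
    if abs(shift_f - shift) > 1e-9:
        raise ValueError(
            f"delay {delay} s is not an integer number of samples at {fs} Hz")
    return _like(resp_sigma1, 0.5 * (np.roll(a, shift, axis=-1) + b))


def normalize_topography(power_map) -> np.ndarray:
    """Divide a per-channel power map by its maximum (output max = 1)."""
    m = np.asarray(power_map, dtype=float)
    peak = m.max()
    if peak <= 0:
        raise ValueError("topography maximum must be positive")
    return m / peak


@dataclass
class ERPPair:
    """Baseline-corrected ERPs to the two syllables of disyllabic words."""

    erp_sigma1: np.ndarray          # channels × samples, window [−0.1, 0.75) s
    erp_sigma2: np.ndarray
    times: np.ndarray               # s relative to syllable onset
    sampling_rate: float
    channel_labels: list[str]
    n_words: int


def disyllabic_erps(recording: EEGRecording, timeline: SyllableTimeline,
                    baseline: float = BASELINE_WINDOW,
                    span: float = ERP_SPAN) -> ERPPair:
    """Average responses to the first (σ1) and second (σ2) syllables of
    disyllabic words, each epoch baseline-corrected on [−0.1, 0) s.

    Epochs that overlap masked artifact samples are excluded word-wise
    (both syllables of the word are dropped together).
    """
    fs = recording.sampling_rate
    n_pre = int(round(baseline * fs))
    n_post = int(round(span * fs))
    mask = getattr(recording, "artifact_mask", None)
    sample_bad = mask.any(axis=0) if mask is not None else None

    di = (timeline.word_length == 2) & timeline.word_onset
    first_idx = np.flatnonzero(di)
    if len(first_idx) == 0:
        raise ValueError("timeline contains no disyllabic words")
    s1_epochs, s2_epochs = [], []
    for i in first_idx:
        if i + 1 >= timeline.n_syllables or timeline.word_id[i + 1] != timeline.word_id[i]:
            continue
        pair = []
        ok = True
        for k in (i, i + 1):
            c = int(round(timeline.onsets[k] * fs))
            i0, i1 = c - n_pre, c + n_post
            if i0 < 0 or i1 > recording.n_samples:
                ok = False
                break
            if sample_bad is not None and sample_bad[i0:i1].any():
                ok = False
                break
            ep = recording.data[:, i0:i1].copy()
            ep -= ep[:, :n_pre].mean(axis=1, keepdims=True)
            pair.append(ep)
        if ok:
            s1_epochs.append(pair[0])
            s2_epochs.append(pair[1])
    if not s1_epochs:
        raise ValueError("no disyllabic word lies fully inside the recording")
    times = (np.arange(n_pre + n_post) - n_pre) / fs
    return ERPPair(np.mean(s1_epochs, axis=0), np.mean(s2_epochs, axis=0),
                   times, fs, list(recording.channel_labels), len(s1_epochs))
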