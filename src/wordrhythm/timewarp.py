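"""Time-warping of responses to naturally timed syllables.

Natural speech has no fixed syllable rate, so syllable- and word-locked
responses are not frequency tagged.  The warp extracts the response
evoked by each syllable (the 0–750 ms window after its onset) and
re-places the segments on a uniform 4-Hz grid by convolution with a
250-ms-spaced impulse train:

    s(t) = sum_j h_j(t) * delta(t − 0.25 j)

Overlapping tails (the 0.25–0.75 s part of each segment) are summed into
the following slots (plain overlap-add, no windowing).  Word-onset flags
travel with the syllable index so that word-locked structure lands on a
2-Hz rhythm in warped time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochedResponse
from .simulate import EEGRecording

__all__ = ["SyllableResponseSet", "WarpedResponse",
           "extract_syllable_responses", "warp_to_isochronous"]

SEGMENT_SPAN = 0.75      # per-syllable response window, s
GRID_STEP = 0.25         # warped syllable spacing (4 Hz), s


@dataclass
class SyllableResponseSet:
    """Per-syllable response segments h_j, channels × samples each."""

    segments: np.ndarray            # syllables × channels × samples
    sampling_rate: float
    channel_labels: list[str]
    word_onset: np.ndarray          # per-syllable flag
    valid: np.ndarray               # False where the segment was boundary-dropped
    log: list = field(default_factory=list)

    @property
    def n_syllables(self) -> int:
        return self.segments.shape[0]


@dataclass
class WarpedResponse:
    """Simulated isochronous response s(t) on the 4-Hz syllable grid."""

    data: np.ndarray                # channels × samples
    sampling_rate: float
    channel_labels: list[str]
    word_onset: np.ndarray

    def to_epochs(self, epoch_duration: float = 7.0) -> EpochedResponse:
        """Cut the warped response into consecutive fixed-length trials.

        Cutting from warped time zero keeps word-rate phase intact: word
        onsets sit on the 0.5-s grid and the epoch length is an integer
        multiple of 0.5 s.
        """
        fs = self.sampling_rate
        n_per = int(round(epoch_duration * fs))
        n_trials = self.data.shape[1] // n_per
        if n_trials == 0:
            raise ValueError("warped response shorter than one epoch")
        trials = self.data[:, : n_trials * n_per].reshape(
            self.data.shape[0], n_trials, n_per).transpose(1, 0, 2)
        return EpochedResponse(trials, fs, list(self.channel_labels),
                               epoch_duration,
                               processing=[f"warp->epochs {n_trials}x{epoch_duration}s"])


def extract_syllable_responses(recording: EEGRecording, onsets,
                               word_onset=None) -> SyllableResponseSet:
    """Slice the 0–750 ms response after every syllable onset.

    Natural syllables are usually shorter than 750 ms, so consecutive
    windows overlap and shared samples appear in both segments — that is
    intentional and part of the warp's definition.  Syllables whose
    window would run past the end of the recording are dropped: their
    slot is kept (grid position preserved) but zero-filled and marked
    invalid, so the 2-Hz phase of the warped output is unaffected.
    """
    fs = recording.sampling_rate
    onsets = np.asarray(onsets, dtype=float)
    if word_onset is None:
        word_onset = np.zeros(len(onsets), dtype=bool)
    word_onset = np.asarray(word_onset, dtype=bool)
    seg_len = int(round(SEGMENT_SPAN * fs))
    n_ch = recording.data.shape[0]
    segments = np.zeros((len(onsets), n_ch, seg_len))
    valid = np.ones(len(onsets), dtype=bool)
    log = []
    for j, on in enumerate(onsets):
        i0 = int(round(on * fs))
        if i0 < 0 or i0 + seg_len > recording.n_samples:
            valid[j] = False
            log.append((j, f"onset {on:.3f}s too close to the recording edge"))
            continue
        segments[j] = recording.data[:, i0:i0 + seg_len]
    return SyllableResponseSet(segments, fs, list(recording.channel_labels),
                               word_onset, valid, log)


def warp_to_isochronous(responses: SyllableResponseSet) -> WarpedResponse:
    """Overlap-add the segments on the 250-ms grid (linear in the inputs)."""
    n_syll = responses.n_syllables
    if n_syll < 2:
        raise ValueError("need at least two syllable segments to warp")
    fs = responses.sampling_rate
    step = int(round(GRID_STEP * fs))
    seg_len = responses.segments.shape[2]
    n_ch = responses.segments.shape[1]
    total = (n_syll - 1) * step + seg_len
    out = np.zeros((n_ch, total))
    for j in range(n_syll):
        if not responses.valid[j]:
            continue
        out[:, j * step: j * step + seg_len] += responses.segments[j]
    return WarpedResponse(out, fs, list(responses.channel_labels),
                          responses.word_onset.copy())
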