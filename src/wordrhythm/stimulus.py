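"""Syllable/word event timelines and stimulus envelopes.

The stimulus design frequency-tags two linguistic levels of a spoken
narrative: syllables are presented at 4 Hz and, in *metrical* stories,
every other syllable is a word onset, so word onsets form a 2-Hz rhythm.
Sentences always contain an even number of syllables; odd-position
syllables within a sentence are labelled σ1 and even-position ones σ2.
A 500-ms silence gap follows every sentence (punctuation position).

Amplitude-modulated variants amplify all σ1 or all σ2 syllables by a
factor of 4, which creates a 2-Hz acoustic rhythm that is either aligned
(σ1) or offset by 250 ms (σ2) relative to the word rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "SyllableTimeline",
    "StimulusEnvelope",
    "generate_metrical_timeline",
    "generate_nonmetrical_timeline",
    "assign_isochronous_timing",
    "assign_natural_timing",
    "apply_amplitude_condition",
    "render_envelope",
    "natural_duration_sampler",
]

#: syllable rate of the isochronous design, Hz
SYLLABLE_RATE = 4.0
#: isochronous syllable duration, s
SYLLABLE_DURATION = 0.250
#: silence inserted at punctuation (two syllable slots), s
GAP_DURATION = 0.500

# synthesized-syllable duration statistics reused as the natural-timing default
NATURAL_DURATION_RANGE = (0.075, 0.354)
NATURAL_DURATION_MEAN = 0.224


@dataclass
class SyllableTimeline:
    """Ordered syllable events with parity, word and amplification labels.

    All per-syllable arrays share one length.  ``parity`` holds 1 for σ1
    (odd position within the sentence, 1-based) and 2 for σ2.  Intervals
    are half-open ``[onset, onset + duration)``; the first onset is at 0
    once timing has been assigned (``onsets`` is NaN before that).
    """

    onsets: np.ndarray
    durations: np.ndarray
    parity: np.ndarray
    word_onset: np.ndarray
    word_id: np.ndarray
    word_length: np.ndarray
    amplified: np.ndarray
    sentence_id: np.ndarray
    gap_after: np.ndarray
    metrical: bool = True

    def __post_init__(self) -> None:
        n = len(self.parity)
        for name in ("onsets", "durations", "parity", "word_onset", "word_id",
                     "word_length", "amplified", "sentence_id", "gap_after"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
            setattr(self, name, arr)

    @property
    def n_syllables(self) -> int:
        return len(self.parity)

    @property
    def has_timing(self) -> bool:
        return bool(np.all(np.isfinite(self.onsets)))

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.durations

    @property
    def span(self) -> float:
        """Time of the last syllable offset, s."""
        return float(self.offsets[-1])

    def validate(self) -> None:
        if self.has_timing and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("syllable onsets must be strictly increasing")
        for sid in np.unique(self.sentence_id):
            if np.count_nonzero(self.sentence_id == sid) % 2:
                raise ValueError(f"sentence {sid} has an odd number of syllables")

    def copy(self) -> "SyllableTimeline":
        return replace(
            self,
            **{name: getattr(self, name).copy()
               for name in ("onsets", "durations", "parity", "word_onset", "word_id",
                            "word_length", "amplified", "sentence_id", "gap_after")},
        )

    def to_events_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset/duration in seconds)."""
        return pd.DataFrame({
            "onset": self.onsets,
            "duration": self.durations,
            "trial_type": np.where(self.parity == 1, "sigma1", "sigma2"),
            "word_onset": self.word_onset.astype(int),
            "word_id": self.word_id,
            "amplified": self.amplified.astype(int),
            "sentence_id": self.sentence_id,
        })


@dataclass
class StimulusEnvelope:
    """Amplitude envelope of the synthesized stimulus (arbitrary units, >= 0)."""

    samples: np.ndarray
    sampling_rate: float
    times: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.times = np.arange(len(self.samples)) / self.sampling_rate


def _default_sentence_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    """Even sentence lengths, uniform over {8, 10, ..., 20} syllables."""
    return rng.choice(np.arange(8, 21, 2), size=n)


def _split_into_sentences(n_syllables: int, rng: np.random.Generator,
                          sentence_length_dist=None) -> list[int]:
    draw = sentence_length_dist or _default_sentence_lengths
    lengths: list[int] = []
    remaining = n_syllables
    while remaining > 0:
        cand = int(draw(rng, 1)[0])
        if cand % 2:
            raise ValueError("sentence lengths must be even")
        if cand >= remaining:
            lengths.append(remaining)
            remaining = 0
        else:
            lengths.append(cand)
            remaining -= cand
    return lengths


def generate_metrical_timeline(n_syllables: int, p_disyllabic: float = 0.77,
                               sentence_length_dist=None,
                               seed: int | None = None) -> SyllableTimeline:
    """Generate a metrical story skeleton (timing unassigned).

    Every σ1 syllable starts a word.  Each σ1/σ2 pair is a disyllabic word
    with probability ``p_disyllabic``, otherwise a pair of monosyllabic
    words, so between two disyllabic words there is always an even number
    of monosyllabic words.

    Parameters
    ----------
    n_syllables : even total number of syllables.
    p_disyllabic : probability that a σ2 syllable is the second syllable
        of a disyllabic word (default 0.77; 0.73 is the alternative
        reported proportion).
    """
    if n_syllables % 2:
        raise ValueError(
            f"n_syllables must be even so sentences pair σ1/σ2; got {n_syllables}")
    if not 0 <= p_disyllabic <= 1:
        raise ValueError("p_disyllabic must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    sentence_lengths = _split_into_sentences(n_syllables, rng, sentence_length_dist)

    parity, word_onset, word_id, word_length, sentence_id, gap_after = \
        [], [], [], [], [], []
    wid = 0
    for sid, slen in enumerate(sentence_lengths):
        for pos in range(slen // 2):
            disyllabic = rng.random() < p_disyllabic
            if disyllabic:
                word_onset += [True, False]
                word_id += [wid, wid]
                word_length += [2, 2]
                wid += 1
            else:
                word_onset += [True, True]
                word_id += [wid, wid + 1]
                word_length += [1, 1]
                wid += 2
            parity += [1, 2]
            sentence_id += [sid, sid]
            gap_after += [False, False]
        gap_after[-1] = True

    n = len(parity)
    tl = SyllableTimeline(
        onsets=np.full(n, np.nan),
        durations=np.full(n, np.nan),
        parity=np.array(parity),
        word_onset=np.array(word_onset),
        word_id=np.array(word_id),
        word_length=np.array(word_length),
        amplified=np.zeros(n, dtype=bool),
        sentence_id=np.array(sentence_id),
        gap_after=np.array(gap_after),
        metrical=True,
    )
    tl.validate()
    return tl


def generate_nonmetrical_timeline(n_syllables: int, word_length_dist=None,
                                  seed: int | None = None,
                                  sentence_length_dist=None,
                                  max_retries: int = 1000) -> SyllableTimeline:
    """Generate a nonmetrical control story skeleton.

    Word lengths are drawn freely (default: 1, 2 or 3 syllables with
    probabilities 0.4/0.45/0.15), sentences still contain an even number
    of syllables, and every sentence must contain at least one odd-position
    syllable that is *not* a word onset, so the word-onset train carries no
    2-Hz periodicity.

    Raises
    ------
    ValueError
        if ``word_length_dist`` cannot satisfy the violation constraint
        (e.g. all-monosyllabic words) within ``max_retries`` attempts.
    """
    if n_syllables % 2:
        raise ValueError(f"n_syllables must be even; got {n_syllables}")
    rng = np.random.default_rng(seed)

    def draw_length() -> int:
        if word_length_dist is None:
            return int(rng.choice([1, 2, 3], p=[0.40, 0.45, 0.15]))
        return int(word_length_dist(rng))

    sentence_lengths = _split_into_sentences(n_syllables, rng, sentence_length_dist)

    parity, word_onset, word_id, word_length, sentence_id, gap_after = \
        [], [], [], [], [], []
    wid = 0
    for sid, slen in enumerate(sentence_lengths):
        for _ in range(max_retries):
            lens: list[int] = []
            total = 0
            while total < slen:
                L = min(draw_length(), slen - total)
                lens.append(L)
                total += L
            onset_flags: list[bool] = []
            for L in lens:
                onset_flags += [True] + [False] * (L - 1)
            # violation: some odd (1-based) position is not a word onset
            if any(not onset_flags[i] for i in range(0, slen, 2)):
                break
        else:
            raise ValueError(
                "word_length_dist cannot produce a sentence with a non-onset "
                "odd-position syllable (all-monosyllabic distributions make "
                "every syllable a word onset)")
        for L in lens:
            for k in range(L):
                word_onset.append(k == 0)
                word_id.append(wid)
                word_length.append(L)
            wid += 1
        parity += [1 if i % 2 == 0 else 2 for i in range(slen)]
        sentence_id += [sid] * slen
        gap_after += [False] * (slen - 1) + [True]

    n = len(parity)
    tl = SyllableTimeline(
        onsets=np.full(n, np.nan),
        durations=np.full(n, np.nan),
        parity=np.array(parity),
        word_onset=np.array(word_onset),
        word_id=np.array(word_id),
        word_length=np.array(word_length),
        amplified=np.zeros(n, dtype=bool),
        sentence_id=np.array(sentence_id),
        gap_after=np.array(gap_after),
        metrical=False,
    )
    tl.validate()
    return tl


def assign_isochronous_timing(timeline: SyllableTimeline) -> SyllableTimeline:
    """Place syllables on the 4-Hz grid: 250-ms slots, 750-ms step across a gap."""
    tl = timeline.copy()
    n = tl.n_syllables
    onsets = np.empty(n)
    t = 0.0
    for i in range(n):
        onsets[i] = t
        t += SYLLABLE_DURATION
        if tl.gap_after[i]:
            t += GAP_DURATION
    tl.onsets = onsets
    tl.durations = np.full(n, SYLLABLE_DURATION)
    tl.validate()
    return tl


@lru_cache(maxsize=8)
def _lognormal_params(lo: float, hi: float, mean: float, sigma: float):
    """mu such that a lognormal(mu, sigma) truncated to [lo, hi] has the given mean."""
    def trunc_mean(mu):
        a = (np.log(lo) - mu) / sigma
        b = (np.log(hi) - mu) / sigma
        num = norm.cdf(b - sigma) - norm.cdf(a - sigma)
        den = norm.cdf(b) - norm.cdf(a)
        return np.exp(mu + sigma ** 2 / 2) * num / den
    mu = brentq(lambda m: trunc_mean(m) - mean, np.log(lo), np.log(hi))
    return mu, sigma


def natural_duration_sampler(rng: np.random.Generator, n: int,
                             sigma: float = 0.30) -> np.ndarray:
    """Syllable durations for natural timing: truncated log-normal.

    Calibrated so that the truncated distribution on 75–354 ms has mean
    224 ms (the duration statistics of the synthesized syllables).
    """
    lo, hi = NATURAL_DURATION_RANGE
    mu, s = _lognormal_params(lo, hi, NATURAL_DURATION_MEAN, sigma)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, s, size=2 * (n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def assign_natural_timing(timeline: SyllableTimeline, duration_dist=None,
                          seed: int | None = None,
                          gap_duration: float = GAP_DURATION) -> SyllableTimeline:
    """Assign natural (jittered) timing: onsets are cumulative drawn durations.

    ``duration_dist(rng, n) -> durations`` defaults to the truncated
    log-normal matched to the 75–354 ms / mean 224 ms syllable statistics.
    Sentence-final syllables are still followed by a ``gap_duration`` pause.
    """
    rng = np.random.default_rng(seed)
    draw = duration_dist or natural_duration_sampler
    tl = timeline.copy()
    n = tl.n_syllables
    durations = np.asarray(draw(rng, n), dtype=float)
    for _ in range(100):
        bad = durations <= 0
        if not bad.any():
            break
        durations[bad] = np.asarray(draw(rng, int(bad.sum())), dtype=float)
    else:
        raise ValueError("duration_dist keeps producing non-positive durations")
    onsets = np.empty(n)
    t = 0.0
    for i in range(n):
        onsets[i] = t
        t += durations[i]
        if tl.gap_after[i]:
            t += gap_duration
    tl.onsets = onsets
    tl.durations = durations
    tl.validate()
    return tl


def apply_amplitude_condition(timeline: SyllableTimeline,
                              condition: str) -> SyllableTimeline:
    """Set amplification flags: 'none', 'sigma1_amplified' or 'sigma2_amplified'."""
    tl = timeline.copy()
    if condition == "none":
        tl.amplified = np.zeros(tl.n_syllables, dtype=bool)
    elif condition == "sigma1_amplified":
        tl.amplified = tl.parity == 1
    elif condition == "sigma2_amplified":
        tl.amplified = tl.parity == 2
    else:
        raise ValueError(
            f"condition must be 'none', 'sigma1_amplified' or 'sigma2_amplified'; "
            f"got {condition!r}")
    return tl


#: amplification factor for amplified syllables
AMPLIFICATION = 4.0
#: cosine offset-taper length at the end of each syllable, s
TAPER_DURATION = 0.025


def render_envelope(timeline: SyllableTimeline,
                    sampling_rate: float) -> StimulusEnvelope:
    """Render the amplitude envelope: unit slots (×4 if amplified), cosine offset taper.

    The envelope is zero during gaps; the last 25 ms of every syllable
    taper monotonically to zero with a cosine quarter-wave.
    """
    if not timeline.has_timing:
        raise ValueError("assign timing before rendering the envelope")
    if sampling_rate < 1.0 / TAPER_DURATION * 2:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz cannot represent the 25-ms taper; "
            "use at least 80 Hz")
    n = int(np.ceil(timeline.span * sampling_rate)) + 1
    env = np.zeros(n)
    for on, dur, amp in zip(timeline.onsets, timeline.durations, timeline.amplified):
        i0 = int(round(on * sampling_rate))
        i1 = int(round((on + dur) * sampling_rate))
        seg = np.full(i1 - i0, AMPLIFICATION if amp else 1.0)
        k = min(int(round(TAPER_DURATION * sampling_rate)), len(seg))
        # cosine quarter-wave ending one sample above zero (next sample is silence)
        seg[len(seg) - k:] *= np.cos(np.pi / 2 * np.arange(1, k + 1) / (k + 1))
        env[i0:i1] = seg
    return StimulusEnvelope(env, sampling_rate)
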