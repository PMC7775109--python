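"""Serialization: BIDS-style events tables, spectrum tables, result records.

Recordings supplied by users in EDF can be loaded through mne (lazy
import); everything the pipeline itself produces travels as plain-text
TSV/JSON so runs are diffable and reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EEGRecording
from .spectral import Spectrum
from .stimulus import SyllableTimeline

__all__ = ["write_events_tsv", "read_events_tsv", "write_spectrum_tsv",
           "write_results_json", "read_recording_edf"]


def write_events_tsv(timeline: SyllableTimeline, path) -> None:
    """Write the timeline as a BIDS-style events TSV (seconds, 6 decimals)."""
    timeline.to_events_frame().to_csv(path, sep="\t", index=False,
                                      float_format="%.6f")


def read_events_tsv(path) -> SyllableTimeline:
    """Reconstruct a timeline from an events TSV written by this package.

    Word lengths and gap flags are re-derived: a word is disyllabic when
    two consecutive rows share a word_id, and a gap follows a syllable
    when the next onset is more than half a syllable late.
    """
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    parity = np.where(df["trial_type"].to_numpy() == "sigma1", 1, 2)
    word_id = df["word_id"].to_numpy()
    counts = pd.Series(word_id).value_counts()
    word_length = np.array([counts[w] for w in word_id])
    onsets = df["onset"].to_numpy(dtype=float)
    durations = df["duration"].to_numpy(dtype=float)
    gap_after = np.zeros(n, dtype=bool)
    gap_after[:-1] = (onsets[1:] - (onsets[:-1] + durations[:-1])) > durations[:-1] / 2
    gap_after[-1] = True
    tl = SyllableTimeline(
        onsets=onsets, durations=durations, parity=parity,
        word_onset=df["word_onset"].to_numpy(dtype=bool),
        word_id=word_id, word_length=word_length,
        amplified=df["amplified"].to_numpy(dtype=bool),
        sentence_id=df["sentence_id"].to_numpy(),
        gap_after=gap_after,
    )
    tl.validate()
    return tl


def write_spectrum_tsv(spectrum: Spectrum, path) -> None:
    """Long-format spectrum: frequency, channel, power, phase_deg."""
    rows = []
    power, phase = spectrum.power, spectrum.phase_deg
    for c, ch in enumerate(spectrum.channel_labels):
        for b, f in enumerate(spectrum.frequencies):
            rows.append((f, ch, power[c, b], phase[c, b]))
    pd.DataFrame(rows, columns=["frequency", "channel", "power", "phase_deg"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_results_json(records: list | dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(records, indent=2, default=default) + "\n")


def read_recording_edf(path) -> EEGRecording:
    """Load a user-supplied EDF recording (requires mne).

    Channel roles are taken from the labels; data are converted to µV.
    """
    try:
        import mne
    except ImportError as err:          # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6         # volts -> µV
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                        reference_state="raw", processing=[f"load_edf {path}"])
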