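# wordrhythm

Frequency-tagging analysis of word and syllable rhythms in EEG responses to
spoken narratives, with a synthetic stimulus-and-EEG generator so that every
stage of the pipeline can be verified without any data download.

## The problem

When a story is synthesized as an isochronous stream of syllables at 4 Hz and
written so that every odd-position syllable (σ1) begins a word, word onsets
repeat at exactly 2 Hz. Neural activity that locks to syllables then appears
as a 4-Hz spectral peak, and activity that locks to words as a 2-Hz peak —
*frequency tagging*. Three further devices complete the design:

* **Amplitude modulation (AM).** Amplifying all σ1 or all σ2 syllables by a
  factor of 4 adds a 2-Hz acoustic rhythm that is aligned (σ1-amplified) or
  offset by 250 ms (σ2-amplified) relative to the words. A response locked to
  word onsets is *identical* in the two conditions (Δφ = 0° at 2 Hz); a
  response locked to the loud syllables is shifted by half a word cycle
  (Δφ = 180°). Averaging the two condition responses therefore cancels the
  AM-locked component (the **word response**); delaying the σ1-amplified
  response by 250 ms before averaging cancels the word-locked component
  instead (the **AM response**).
* **Time-warping.** Natural speech has irregular syllable durations
  (75–354 ms, mean 224 ms), so nothing is tagged. Extracting the response
  h_j(t) evoked by each syllable (0–750 ms after its onset) and convolving
  with a 4-Hz impulse train, s(t) = Σ_j h_j(t) ∗ δ(t − 0.25 j), simulates the
  response to isochronous speech and restores the tags.
* **Statistics.** Peaks are measured as power at the target bin minus the
  mean power of the four neighbouring bins (two per side, 1/7-Hz resolution
  from 7-s trials), tested with a participant-level bootstrap
  (10,000 resamples, p-floor 1/10,001, BCa confidence intervals), circular
  statistics for phase (circular means, shortest-arc CIs, a uniform-null
  phase-coherence test), FDR correction, and a cluster-based permutation test
  (2,000 permutations) for ERP differences between the two syllables of
  disyllabic words.

The package implements the full chain — stimulus timelines, forward EEG
simulation, preprocessing (downsampling to 128 Hz, mastoid re-referencing,
0.8–30 Hz linear-phase FIR with delay compensation, EOG regression, artifact
masking, sentence-aware 7-s segmentation, trial rejection), spectra and phase,
time-warping, word/AM separation, and the inferential layer — as a Python
library for researchers who analyse steady-state/frequency-tagged EEG or want
a fully synthetic testbed for such pipelines.

## Worked example

```python
import wordrhythm as wr
from wordrhythm import preprocess as pp

timeline = wr.assign_isochronous_timing(wr.generate_metrical_timeline(1400, seed=3))
config = wr.SimulationConfig(sampling_rate=128.0, amplitude_word=0.8,
                             amplitude_syllable=1.0, noise_sd=6.0,
                             eog_gain=0.05, seed=4)
recording = wr.preprocess_recording(wr.simulate_recording(timeline, config))
epochs = pp.reject_trials(pp.segment_trials(recording, timeline))
spectrum = wr.average_and_spectrum(epochs)
for f in (2.0, 4.0):
    print(f, wr.peak_minus_neighbors(spectrum, f)[1])
```

prints (examples/02_simulate_and_spectrum.py):

```
kept 42 trials of 7 s (frequency resolution 0.143 Hz)
2 Hz: peak-minus-neighbours power = 0.0016 uV^2 ...
4 Hz: peak-minus-neighbours power = 0.0080 uV^2 ...
```

Both tagged peaks stand above the 1/f background: the 4-Hz value is the
syllable response, the 2-Hz value the word response. The `examples/`
directory holds one short script per capability (stimulus design, simulation
and spectra, phase and word/AM separation, time-warping of natural timing,
and the statistics layer); each prints the numbers it computes and a line on
what they mean. `wordrhythm.run_pipeline(RunConfig(preset="exp1_isochronous"))`
orchestrates a whole simulated experiment (four presets: isochronous
attentive, passive movie-watching, natural timing with warping, and the
amplified-speech replication) into a JSON report.

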