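# Methods

This note documents the models, conventions and numerical choices behind
`wordrhythm`, in the order data flow through the pipeline.

## Stimulus model

A story is a sequence of sentences, each with an even number of syllables.
Within a sentence, odd positions are σ1 and even positions σ2 (1-based).
Timing is half-open `[onset, onset + duration)` with the first syllable at
t = 0.

* **Metrical stories** are built from σ1/σ2 pairs: with probability
  `p_disyllabic` a pair is one disyllabic word, otherwise two monosyllabic
  words, so every σ1 starts a word and between two disyllabic words there is
  always an even number of monosyllables. `p_disyllabic` defaults to 0.77;
  0.73 is retained as an alternative preset because both proportions are in
  circulation for this design. Note that 23% of σ2 syllables are themselves
  (monosyllabic) word onsets: the *word-onset* train is exactly 2-Hz periodic
  only in the all-disyllabic limit, while the σ1 train always is.
* **Nonmetrical stories** draw word lengths freely (default 1/2/3 syllables
  with probabilities 0.40/0.45/0.15) under the constraint that every sentence
  contains at least one odd-position syllable that is not a word onset; an
  all-monosyllabic distribution makes the constraint unsatisfiable and is
  rejected after bounded retries.
* **Sentence lengths** are drawn uniformly from {8, 10, …, 20} syllables
  (configurable); only story-level word counts are fixed by the design, so a
  distribution had to be chosen.
* **Isochronous timing**: 250-ms syllables, a 500-ms silence after each
  sentence (the punctuation position). Every removable span — the gap and
  the first two syllables of a sentence — is an integer multiple of the
  500-ms word period, which is what makes excision phase-safe (below).
* **Natural timing** draws syllable durations from a log-normal truncated to
  75–354 ms whose truncated mean is calibrated to 224 ms (the published
  duration statistics of the synthesized syllables); the log-sd 0.30 is a
  free choice setting a realistic spread within that range.
* **Envelopes**: unit-amplitude syllable slots, ×4 where amplified, a 25-ms
  cosine offset taper, zeros in gaps. Only the amplitude envelope is
  rendered; no carrier fine structure.

## Forward EEG model

The response model is linear:
`data = Σ_c a_c · topo_c ⊗ (kernel_c ∗ train_c) + noise + EOG leakage`,
with components c ∈ {word, syllable, AM} whose impulse trains are the word
onsets, all syllable onsets, and the amplified-syllable onsets. Kernels are
unit-peak single-lobe shapes (gamma or windowed sine) with support inside
0–0.75 s — keeping the support inside one 0.75-s span is also what makes the
σ1/σ2 phase identities exact (below). Topographies are per-channel weights
with max 1; defaults are centro-frontal for word/syllable and temporal for
AM, mirroring where the word/AM contrast is largest. Channels are the 64
BioSemi 10-10 positions plus HEOG, VEOG, M1, M2.

Background noise is Gaussian with a 1/f^α spectrum (α = 1 by default), drawn
directly in the frequency domain in single precision for speed and scaled to
the requested per-channel sd. Ocular activity is a detrended random walk on
the EOG channels leaked into frontal channels with gain `eog_gain`; the
generator does not model how real ocular artifacts arise, only enough
structure for the regression stage to have a recoverable ground truth.
Occasional large transients (Hann bursts of 300–800 µV, Poisson rate
`artifact_rate`, default 0.015/s in the experiment presets ≈ 10% of 7-s
trials affected) exercise masking and trial rejection; the base
`SimulationConfig` default is 0 so that noise-free runs stay exact.
Between-subject variability is log-normal amplitude scaling and Gaussian
latency jitter (whole-sample kernel shifts); no generative model is
published for these, so both default to documented, configurable values.

The default recording rate is 2048 Hz (the acquisition rate the pipeline is
built around); a 128-Hz fast mode skips the downsampling stage and is used
wherever an analysis starts at the analysis rate anyway.

## Preprocessing

Canonical order, audited via the provenance list on each recording:
downsample (anti-aliased polyphase, integer factor, 2048 → 128 Hz) →
mastoid re-reference (EEG minus (M1+M2)/2) → band-pass FIR → EOG regression
(ordinary least squares of HEOG/VEOG out of every EEG channel via normal
equations; residuals are orthogonal to both regressors) → masking of samples
exceeding 1 mV.

The FIR is a Hamming-windowed sinc with `6 s × fs + 1` taps (odd, so the
group delay N/2 is an integer sample count), passband 0.8–30 Hz, −6 dB at
the cutoffs by construction. Delay compensation removes the first N/2
samples of the causal output, re-aligning it with the input; the trailing
N/2 samples are lost to the delay. An impulse at sample k stays at sample k.

Segmentation excises each sentence's first two syllables (500 ms of
sound-onset response) and all gaps, concatenates the remainder, and cuts
consecutive 7-s trials (896 samples at 128 Hz), discarding the leftover
tail. Because every excised span is a multiple of 0.5 s, a 2-Hz probe
remains phase-continuous across every splice. Trial rejection is an
automated stand-in for visual inspection: a trial is dropped if it contains
masked samples, exceeds 200 µV peak-to-peak, or exceeds 4× the median trial
variance; all decisions are logged. Masked samples cause rejection rather
than interpolation — the conservative choice where no rule is prescribed.

## Spectra and phase

Trials are averaged coherently in the time domain and the mean is DFT'd
without a taper, giving 1/7-Hz resolution; coefficients are divided by the
sample count and power is the squared magnitude (normalization is a free
choice; every comparison in the pipeline is invariant to it). Phase is
cosine-referenced with time zero at trial start, reported in (−180°, 180°].
The peak statistic is power at the target bin minus the mean of the four
neighbouring bins. Power is averaged over channels then participants;
phases are only ever combined with circular means (the mean direction is
flagged undefined when the resultant length is ≈ 0, e.g. antipodal pairs).

Two deliberate subtleties, both verified in the test suite:

* The σ1-/σ2-amplified AM trains are global 250-ms translates, so the
  AM-locked responses are too, and because kernels live inside 0.75 s and
  all segment boundaries sit on the 0.5-s grid, the 2-Hz phase difference of
  the segmented, trial-averaged spectra is **exactly** 180°. The band-pass
  filter, however, stretches the effective response beyond 0.75 s; its
  sentence-onset transients interact with excision and blur the identity by
  a few tenths of a degree (and polyphase resampling by ~10⁻⁴ °). The phase
  identities are therefore measured on the response model (segmentation +
  spectra without the band-pass); the filtered chain reproduces them
  approximately.
* Excision gating is multiplication by a window whose spectrum has a comb at
  multiples of 2 Hz, so near-DC and 4-Hz response content leaks
  deterministically into the measured 2-Hz bin. This is a property of the
  gap design shared by measurement and any noise-free reference computed
  through the same path; comparisons are therefore always made
  reference-vs-measurement through identical paths.

## Time-warping

`extract_syllable_responses` slices 0–750 ms after every onset (overlapping
windows are intentional); syllables too close to the recording edge keep
their grid slot but are zero-filled, preserving 2-Hz phase.
`warp_to_isochronous` overlap-adds the segments at 250-ms spacing — plain
convolution with the impulse train, no windowing or crossfade. Consequences
worth knowing: warping an already-isochronous recording reproduces each
quarter-cycle scaled by the number of covering windows (up to 3), and for
natural timing the duplicated kernel copies enter with timing jitter, which
slightly biases warped phase; the warped word peak remains exactly on the
2-Hz bin. Word-onset flags travel with the syllable index, and warped
responses re-enter the standard epoching/spectral path.

## Word/AM separation and ERPs

`word_average` is the elementwise condition mean; `am_average` first delays
the σ1-amplified response by 250 ms (exactly 32 samples at 128 Hz;
non-integer shifts are rejected rather than interpolated). The delay wraps
circularly within each 7-s trial: trials are phase-continuous and contain an
integer number of word cycles, so the wrap preserves exact 2-Hz antiphase
cancellation — noise-free cancellation is at machine precision (relative
2-Hz power < 10⁻²⁰). Topographies are normalized by their maximum for
shape comparisons. ERPs are extracted for disyllabic words only, in a
[−0.1, 0.75) s window per syllable, baseline-corrected by the 100-ms
pre-onset mean; words overlapping masked samples are dropped word-wise.

## Statistics

All tests resample participants with replacement; everything is
deterministic given a seed, and permutation/bootstrap p-values respect the
1/(n+1) floor.

* `bootstrap_engine`: 10,000 resamples; BCa intervals with the bias term
  from the fraction of resampled statistics below the point estimate (ties
  split evenly) and acceleration from the leave-one-out jackknife skewness.
  BCa is known to undercover at n = 16 (~91% for a nominal 95% on normal
  data — scipy's implementation measures the same); coverage reaches the
  nominal level by n ≈ 100. Reported as-is rather than widened.
* `spectral_peak_test` (one-sided): p = (N+1)/(B+1) with N the resampled
  means ≤ 0, reproducing the p = 0.0001 floor when every resample is
  positive. Empirical size ≈ 0.08 at α = 0.05, n = 16.
* `power_difference_test` (two-sided, paired): the literal "count the
  minority-side resampled means" rule has empirical size ≈ 0.12 at n = 16,
  so the test instead resamples the *centred* differences and compares the
  studentized mean, keeping the (2N+1)/(B+1) form with N the null resamples
  at least as extreme in the minority direction (ties conservative).
  Empirical size ≈ 0.06. The BCa CI of the raw mean difference is reported
  alongside.
* `cross_experiment_test` (independent groups): the default resamples both
  groups and tests the sign of the difference of resampled means — locating
  one group's observed mean inside the *other* group's bootstrap
  distribution (`method="percentile"`, kept for reference) ignores the
  located mean's own sampling variability and its size is ≈ 0.17 at n = 16.
* `phase_difference_ci`: shortest arc over the resampled phase values
  containing V% of them (returned endpoints may wrap across ±180°); with
  ~2,000+ resamples its coverage is close to nominal.
* `phase_coherence_test`: resultant length across participants against
  10,000 uniform-phase null draws.
* `fdr_adjust`: Benjamini–Hochberg step-up (statsmodels); each reported
  comparison group is treated as one family.
* `cluster_permutation_test`: pointwise paired t, two-sided threshold at
  the cluster-forming α (default 0.05 — not prescribed, configurable),
  sign-separated maximal runs, summed t as the cluster statistic, and a
  within-participant condition-exchange (sign-flip) null over 2,000
  permutations with the max-|cluster| statistic; ties count as ≥. The
  sign-flip scheme is the exchangeable-valid randomization for paired data.
* `paired_effect_size`: Cohen's d of paired differences, achieved power via
  the noncentral t at the two-sided α.

Empirical type-I error of all five tests sits in [0.02, 0.09] at α = 0.05
(verified over 200 null replicates with 1,000 bootstrap / 500 permutation
resamples in the acceptance suite).

## Pipeline presets and problem sizes

`run_pipeline` wires the stages for four experiment layouts (isochronous
attentive; passive movie-watching, modelled as a zero word-locked
component; natural timing routed through the warp; the amplified-speech
replication with n = 20 and 104 trials). Story length is derived from the
trial target (148 trials of 7 s for the first three presets). The
acceptance script runs the noise-free design-logic checks on ~20-sentence
stories (≈ 8 trials) at the full 2048-Hz recording rate — these quantities
are deterministic and independent of story length — and the natural-timing
check on a ~40-sentence story. The parameter-recovery check keeps the full
148 trials × 16 participants but simulates at the 128-Hz analysis rate with
zero between-subject variability, so "injected value" is well defined; its
single-trial 2-Hz SNR is calibrated to −10 dB by measuring signal-bin and
unit-noise-bin power in two auxiliary simulations.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the real recordings — event
timing, component locking, 1/f background, ocular leakage, occasional
artifacts, between-subject spread — but not volume conduction from real
sources, non-stationary rhythms, or any relation between comprehension and
response amplitude. Passing tests therefore demonstrate that the analysis
chain measures what it claims to measure on data of known composition
(correctness), not that any neural claim holds; conversely, headline
empirical quantities from real EEG (specific phase-difference angles,
topography contrasts, attention effects) are design targets the synthetic
pipeline can emulate qualitatively but cannot re-derive.

## Known limitations

EDF input is read-only (via mne) and not exercised by the test suite; there
is no ICA, bad-channel interpolation, or channel-adjacency clustering
(clusters are temporal only); the warp assumes responses are strictly
time-locked to onsets; and the percentile-style bootstrap tests remain
mildly liberal at n = 16 even after the calibration choices above.
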