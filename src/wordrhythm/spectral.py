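"""Coherent trial averaging, DFT spectra, frequency-tagged peak statistics
and circular phase measures.

The response averaged over trials (coherent averaging, which preserves
phase-locked components and suppresses background activity as 1/n) is
transformed with a plain DFT — no taper — so the frequency resolution is
1/epoch-duration = 1/7 Hz for the canonical 7-s trials.  Coefficients are
normalized by the sample count; power is the squared magnitude.  Phase is
cosine-referenced with time zero at trial start, reported in degrees in
(−180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedResponse

__all__ = [
    "Spectrum", "PhaseStat", "average_and_spectrum", "peak_minus_neighbors",
    "circular_mean", "condition_phase_difference", "wrap_degrees",
    "grand_average_power",
]


def wrap_degrees(angle) -> np.ndarray | float:
    """Wrap angles in degrees to (−180, 180]."""
    wrapped = -(np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0)
    return wrapped


@dataclass
class Spectrum:
    """One-sided complex spectrum per channel, bin spacing 1/epoch_duration."""

    coefficients: np.ndarray        # channels × bins, complex
    frequencies: np.ndarray         # Hz
    epoch_duration: float
    channel_labels: list[str]
    n_trials_averaged: int = 1

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def phase_deg(self) -> np.ndarray:
        return wrap_degrees(np.degrees(np.angle(self.coefficients)))

    def bin_index(self, freq: float, tol: float = 1e-6) -> int:
        """Index of the bin at ``freq``; error if ``freq`` is off the grid."""
        pos = freq * self.epoch_duration
        idx = int(round(pos))
        if abs(pos - idx) > tol or not 0 <= idx < len(self.frequencies):
            raise ValueError(
                f"{freq} Hz is not on the {1 / self.epoch_duration:.6g}-Hz bin grid")
        return idx

    @property
    def eeg_indices(self) -> np.ndarray:
        from .simulate import AUX_CHANNELS
        aux = set(AUX_CHANNELS)
        return np.array([i for i, ch in enumerate(self.channel_labels)
                         if ch not in aux])


@dataclass
class PhaseStat:
    """Circular mean direction and resultant length of a set of phases."""

    mean_angle: float               # degrees in (−180, 180]
    resultant_length: float         # in [0, 1]
    n: int
    defined: bool = True


def average_and_spectrum(epochs: EpochedResponse) -> Spectrum:
    """Average trials in the time domain, then DFT each channel (no taper)."""
    if epochs.n_trials < 1:
        raise ValueError("no kept trials to average")
    mean = epochs.data.mean(axis=0)
    n = mean.shape[-1]
    coeffs = np.fft.rfft(mean, axis=-1) / n
    freqs = np.fft.rfftfreq(n, 1.0 / epochs.sampling_rate)
    return Spectrum(coeffs, freqs, epochs.epoch_duration,
                    list(epochs.channel_labels), epochs.n_trials)


def peak_minus_neighbors(spectrum: Spectrum, f_target: float, n_side: int = 2,
                         eeg_only: bool = True):
    """Target-bin power minus the mean power of ``2 * n_side`` neighbour bins.

    Returns ``(per_channel, channel_average)``.  The neighbours of 2 Hz at
    1/7-Hz resolution are the bins at 2 ± 1/7 and 2 ± 2/7 Hz.
    """
    idx = spectrum.bin_index(f_target)
    if idx - n_side < 0 or idx + n_side >= spectrum.coefficients.shape[1]:
        raise ValueError("not enough neighbour bins around the target frequency")
    power = spectrum.power
    if eeg_only and len(spectrum.channel_labels) > 1:
        power = power[spectrum.eeg_indices]
    neigh = np.concatenate([np.arange(idx - n_side, idx),
                            np.arange(idx + 1, idx + n_side + 1)])
    stat = power[:, idx] - power[:, neigh].mean(axis=1)
    return stat, float(stat.mean())


def circular_mean(angles_deg, weights=None, tol: float = 1e-12) -> PhaseStat:
    """Circular mean via the mean resultant vector.

    The mean direction is undefined (``defined=False``) when the resultant
    length is below ``tol`` — e.g. for antipodal angle pairs.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise ValueError("need at least one angle")
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    z = np.sum(weights * np.exp(1j * np.radians(angles))) / np.sum(weights)
    r = float(np.abs(z))
    if r < tol:
        return PhaseStat(mean_angle=float("nan"), resultant_length=r,
                         n=angles.size, defined=False)
    return PhaseStat(mean_angle=float(wrap_degrees(np.degrees(np.angle(z)))),
                     resultant_length=r, n=angles.size, defined=True)


def condition_phase_difference(spec_a: Spectrum, spec_b: Spectrum, freq: float,
                               eeg_only: bool = True):
    """Per-channel phase difference arg(a) − arg(b) at ``freq``, plus summary.

    Returns ``(per_channel_deg, summary)`` where the summary is the
    circular mean across channels.  Antisymmetric:
    Δφ(a, b) = −Δφ(b, a) (mod 360°).
    """
    if (spec_a.epoch_duration != spec_b.epoch_duration
            or spec_a.coefficients.shape != spec_b.coefficients.shape):
        raise ValueError("spectra are on different bin grids")
    idx = spec_a.bin_index(freq)
    ca, cb = spec_a.coefficients[:, idx], spec_b.coefficients[:, idx]
    if eeg_only and len(spec_a.channel_labels) > 1:
        sel = spec_a.eeg_indices
        ca, cb = ca[sel], cb[sel]
    diff = wrap_degrees(np.degrees(np.angle(ca) - np.angle(cb)))
    return diff, circular_mean(diff)


def grand_average_power(spectra: list, eeg_only: bool = True) -> np.ndarray:
    """Power averaged over channels then participants (one row per spectrum)."""
    rows = []
    for s in spectra:
        p = s.power[s.eeg_indices] if eeg_only else s.power
        rows.append(p.mean(axis=0))
    return np.mean(rows, axis=0)
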