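"""Inferential machinery for frequency-tagged responses.

Bootstrap tests resample participants with replacement (default 10,000
resamples); p-values follow the convention p = (N + 1)/(n_resamples + 1)
where N counts the resamples that do NOT support the alternative, giving
the floor p = 1/10,001 ≈ 0.0001 when every resample supports it.
Confidence intervals are bias-corrected and accelerated (BCa), with the
acceleration term from a leave-one-participant-out jackknife.  Circular
confidence intervals are shortest arcs over resampled phase values; the
phase-coherence null is uniform phase.  The ERP comparison uses a
cluster-based permutation test with temporal-adjacency clusters, summed
t-values as cluster statistics and within-participant condition-label
exchange (sign flipping) as the randomization (2,000 permutations).
Multiple comparisons are corrected with the Benjamini–Hochberg false
discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .spectral import wrap_degrees

__all__ = [
    "StatResult", "ClusterResult", "BootstrapResult", "bootstrap_engine",
    "spectral_peak_test", "power_difference_test", "cross_experiment_test",
    "phase_difference_ci", "phase_coherence_test", "fdr_adjust",
    "cluster_permutation_test", "paired_effect_size",
]

N_RESAMPLES = 10_000
N_PERMUTATIONS = 2_000


@dataclass
class StatResult:
    statistic: float
    p_value: float
    n_resamples: int
    sidedness: str
    ci: tuple | None = None
    fdr_adjusted_p: float | None = None
    seed: int | None = None
    degenerate: bool = False

    def to_record(self, test: str) -> dict:
        return {"test": test, "statistic": self.statistic, "p": self.p_value,
                "p_fdr": self.fdr_adjusted_p, "ci": self.ci,
                "n_resamples": self.n_resamples, "seed": self.seed}


@dataclass
class BootstrapResult:
    point_estimate: float
    distribution: np.ndarray
    ci: tuple
    bias_z0: float
    acceleration: float
    degenerate: bool = False


def _resample_matrix(rng: np.random.Generator, n: int, n_resamples: int):
    return rng.integers(0, n, size=(n_resamples, n))


def bootstrap_engine(values, statistic=None, n_resamples: int = N_RESAMPLES,
                     seed: int | None = None, coverage: float = 95.0) -> BootstrapResult:
    """Participant-level bootstrap with a BCa confidence interval.

    ``statistic`` maps a resampled value vector to a scalar (default:
    mean).  The bias term z0 comes from the fraction of resampled
    statistics below the point estimate; the acceleration from the
    jackknife skewness.  With n = 1 the result is flagged degenerate
    (zero-width CI).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 1:
        raise ValueError("need at least one value")
    stat = statistic or (lambda v: float(np.mean(v)))
    theta = stat(values)
    rng = np.random.default_rng(seed)
    idx = _resample_matrix(rng, n, n_resamples)
    if statistic is None:
        dist = values[idx].mean(axis=1)
    else:
        dist = np.array([stat(values[row]) for row in idx])
    if n < 2 or np.allclose(dist, dist[0]):
        return BootstrapResult(theta, dist, (theta, theta), 0.0, 0.0,
                               degenerate=True)
    # bias correction: ties split evenly to keep z0 finite and symmetric
    frac = (np.sum(dist < theta) + 0.5 * np.sum(dist == theta)) / n_resamples
    frac = np.clip(frac, 0.5 / n_resamples, 1 - 0.5 / n_resamples)
    z0 = sps.norm.ppf(frac)
    jack = np.array([stat(np.delete(values, i)) for i in range(n)])
    d = jack.mean() - jack
    denom = 6.0 * np.sum(d ** 2) ** 1.5
    a = np.sum(d ** 3) / denom if denom > 0 else 0.0
    alpha = (1 - coverage / 100.0) / 2.0
    lo_hi = []
    for za in (sps.norm.ppf(alpha), sps.norm.ppf(1 - alpha)):
        adj = sps.norm.cdf(z0 + (z0 + za) / (1 - a * (z0 + za)))
        lo_hi.append(float(np.percentile(dist, 100 * adj)))
    return BootstrapResult(theta, dist, tuple(lo_hi), float(z0), float(a))


def _floor_p(n_contra: int, n_resamples: int) -> float:
    return (n_contra + 1) / (n_resamples + 1)


def spectral_peak_test(per_participant_values, n_resamples: int = N_RESAMPLES,
                       seed: int | None = None) -> StatResult:
    """One-sided bootstrap test that the neighbour-corrected peak power > 0.

    p = (N + 1)/(n_resamples + 1) with N the number of resampled means
    ≤ 0; a uniformly positive resampling distribution gives the floor
    p = 1/10,001 ≈ 0.0001.
    """
    boot = bootstrap_engine(per_participant_values, n_resamples=n_resamples,
                            seed=seed)
    n_contra = int(np.sum(boot.distribution <= 0))
    return StatResult(boot.point_estimate, _floor_p(n_contra, n_resamples),
                      n_resamples, "one-sided", ci=boot.ci, seed=seed,
                      degenerate=boot.degenerate)


def power_difference_test(values_a, values_b, n_resamples: int = N_RESAMPLES,
                          seed: int | None = None) -> StatResult:
    """Two-sided paired bootstrap test of a power difference.

    The paired differences are centred to impose the null, resampled with
    replacement, and compared through the studentized mean (mean over its
    resampled standard error), which keeps the test close to its nominal
    size at small n where raw percentile counting runs liberal.  With N
    the count of null resamples at least as extreme as the observed
    statistic in the minority direction (ties counted conservatively),
    p = (2N + 1)/(n_resamples + 1), capped at 1.  The BCa confidence
    interval for the mean difference is reported alongside.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired conditions must have equal length")
    d = a - b
    n = len(d)
    boot = bootstrap_engine(d, n_resamples=n_resamples, seed=seed)
    if boot.degenerate or d.std(ddof=1) == 0:
        p = 1.0 if np.allclose(d, 0) else 1.0 / (n_resamples + 1)
        return StatResult(float(d.mean()), p, n_resamples, "two-sided",
                          ci=boot.ci, seed=seed, degenerate=True)

    def studentized(samples):
        m = samples.mean(axis=-1)
        s = samples.std(axis=-1, ddof=1)
        s = np.where(s == 0, np.inf, s)
        return m / (s / np.sqrt(n))

    t_obs = float(studentized(d[None, :])[0])
    rng = np.random.default_rng(seed)
    centred = d - d.mean()
    t_null = studentized(centred[_resample_matrix(rng, n, n_resamples)])
    # ties sit in both tail counts, which keeps the smaller tail conservative
    n_hi = int(np.sum(t_null >= t_obs))
    n_lo = int(np.sum(t_null <= t_obs))
    p = min(1.0, (2 * min(n_hi, n_lo) + 1) / (n_resamples + 1))
    return StatResult(float(d.mean()), p, n_resamples, "two-sided",
                      ci=boot.ci, seed=seed)


def cross_experiment_test(values_a, values_b, n_resamples: int = N_RESAMPLES,
                          seed: int | None = None,
                          method: str = "difference") -> StatResult:
    """Two-sided comparison of independent groups via bootstrap means.

    ``method='difference'`` (default) resamples both groups independently
    and tests the sign of the difference of resampled means — a correctly
    sized two-sample bootstrap.  ``method='percentile'`` locates one
    group's observed mean within the other group's bootstrap-mean
    distribution; it is kept for reference but is anticonservative for
    small groups because it ignores the sampling variability of the
    located mean.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    rng = np.random.default_rng(seed)
    dist_a = a[_resample_matrix(rng, len(a), n_resamples)].mean(axis=1)
    dist_b = b[_resample_matrix(rng, len(b), n_resamples)].mean(axis=1)
    stat = float(a.mean() - b.mean())
    if method == "difference":
        d = dist_a - dist_b
        n_pos = int(np.sum(d > 0))
        n_neg = int(np.sum(d < 0))
        ties = n_resamples - n_pos - n_neg
        p = min(1.0, (2 * (min(n_pos, n_neg) + ties) + 1) / (n_resamples + 1))
    elif method == "percentile":
        q = (np.sum(dist_a < b.mean()) + 0.5 * np.sum(dist_a == b.mean()))
        n_contra = int(min(q, n_resamples - q))
        p = min(1.0, (2 * n_contra + 1) / (n_resamples + 1))
    else:
        raise ValueError("method must be 'difference' or 'percentile'")
    return StatResult(stat, p, n_resamples, "two-sided", seed=seed)


def phase_difference_ci(resampled_deg, coverage: float = 95.0) -> tuple:
    """Shortest arc containing ``coverage`` % of resampled phase values.

    Returns ``(lo, hi)`` in degrees wrapped to (−180, 180]; ``hi`` may be
    numerically smaller than ``lo`` when the arc crosses ±180°.  With
    coverage 100 and dispersed samples the full circle is returned.
    """
    if not 0 < coverage <= 100:
        raise ValueError("coverage must lie in (0, 100]")
    angles = np.sort(np.mod(np.asarray(resampled_deg, dtype=float), 360.0))
    B = len(angles)
    m = int(np.ceil(coverage / 100.0 * B))
    if m >= B:
        # cover all points: the shortest such arc is the complement of the
        # largest gap between adjacent (circularly ordered) values
        gaps = np.diff(np.concatenate([angles, angles[:1] + 360.0]))
        k = int(np.argmax(gaps))
        lo = angles[(k + 1) % B]
        hi = angles[k]
        return (float(wrap_degrees(lo)), float(wrap_degrees(hi)))
    ext = np.concatenate([angles, angles + 360.0])
    widths = ext[m - 1: m - 1 + B] - ext[:B]
    k = int(np.argmin(widths))
    return (float(wrap_degrees(ext[k])), float(wrap_degrees(ext[k + m - 1])))


def phase_coherence_test(phases_deg, n_null: int = N_RESAMPLES,
                         seed: int | None = None) -> StatResult:
    """Inter-participant phase coherence against a uniform-phase null.

    The statistic is the resultant length R of the participants' phases;
    the null distribution is R for the same n of uniformly random phases,
    and p = (#{R_null ≥ R} + 1)/(n_null + 1).
    """
    phases = np.asarray(phases_deg, dtype=float)
    n = len(phases)
    if n < 2:
        raise ValueError("need at least two phases")
    r_obs = float(np.abs(np.mean(np.exp(1j * np.radians(phases)))))
    rng = np.random.default_rng(seed)
    null = np.abs(np.mean(np.exp(1j * rng.uniform(0, 2 * np.pi, (n_null, n))),
                          axis=1))
    n_ge = int(np.sum(null >= r_obs))
    return StatResult(r_obs, _floor_p(n_ge, n_null), n_null, "one-sided",
                      seed=seed)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ClusterResult:
    clusters: list                  # (t_start, t_end) seconds, half-open
    cluster_stats: list             # signed sums of t-values
    cluster_p: list
    n_permutations: int
    t_values: np.ndarray = None
    threshold: float = None

    @property
    def significant(self) -> list:
        return [c for c, p in zip(self.clusters, self.cluster_p) if p < 0.05]


def _clusters_from_t(t: np.ndarray, thresh: float):
    """Maximal suprathreshold runs, clustered separately by sign."""
    out = []
    for sign in (+1, -1):
        supra = sign * t > thresh
        if not supra.any():
            continue
        edges = np.diff(supra.astype(int))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if supra[0]:
            starts.insert(0, 0)
        if supra[-1]:
            ends.append(len(t))
        for s, e in zip(starts, ends):
            out.append((s, e, float(t[s:e].sum())))
    return out


def cluster_permutation_test(erp_a, erp_b, n_permutations: int = N_PERMUTATIONS,
                             cluster_alpha: float = 0.05,
                             seed: int | None = None,
                             sampling_rate: float = 128.0,
                             t_start: float = 0.0) -> ClusterResult:
    """Cluster-based permutation test of paired ERPs (participants × samples).

    Pointwise paired t-values are thresholded at the two-sided
    ``cluster_alpha`` critical value; suprathreshold runs are clustered by
    temporal adjacency; the cluster statistic is the sum of t-values.  The
    permutation null swaps the two conditions within participants (sign
    flips of the paired differences) and records the maximum absolute
    cluster statistic; ties count as ≥ (conservative).  Cluster intervals
    are reported in seconds, relative to ``t_start``.
    """
    a = np.asarray(erp_a, dtype=float)
    b = np.asarray(erp_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("erp_a and erp_b must be participants × samples, equal shape")
    n, n_t = a.shape
    if n < 2:
        raise ValueError("need at least two participants")
    d = a - b
    thresh = sps.t.ppf(1 - cluster_alpha / 2, n - 1)

    def t_vals(mean, msq):
        var = (msq - mean ** 2) * n / (n - 1)
        var = np.maximum(var, 1e-300)
        return mean / np.sqrt(var / n)

    msq = (d ** 2).mean(axis=0)
    t_obs = t_vals(d.mean(axis=0), msq)
    obs_clusters = _clusters_from_t(t_obs, thresh)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    null_max = np.zeros(n_permutations)
    means = signs @ d / n          # permuted means; per-sample msq is invariant
    for i in range(n_permutations):
        tp = t_vals(means[i], msq)
        cl = _clusters_from_t(tp, thresh)
        null_max[i] = max((abs(s) for *_, s in cl), default=0.0)

    clusters, stats_, ps = [], [], []
    for s_idx, e_idx, cs in obs_clusters:
        p = (int(np.sum(null_max >= abs(cs))) + 1) / (n_permutations + 1)
        clusters.append((t_start + s_idx / sampling_rate,
                         t_start + e_idx / sampling_rate))
        stats_.append(cs)
        ps.append(p)
    return ClusterResult(clusters, stats_, ps, n_permutations, t_obs, thresh)


def paired_effect_size(values_target, values_reference,
                       alpha: float = 0.05) -> tuple[float, float]:
    """Cohen's d for paired differences and achieved power of the paired t-test.

    d = mean(diff)/sd(diff); the achieved power uses the noncentral t
    distribution with noncentrality d·sqrt(n) at the two-sided ``alpha``
    critical value.
    """
    x = np.asarray(values_target, dtype=float)
    y = np.asarray(values_reference, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired samples with n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; d is undefined")
    d = float(diff.mean() / sd)
    n = len(diff)
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    power = float(1 - sps.nct.cdf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))
    return d, power
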