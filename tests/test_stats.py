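"""Bootstrap, circular, FDR and cluster-permutation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wordrhythm as wr
from wordrhythm.spectral import wrap_degrees


class TestBootstrapEngine:
    def test_single_value_degenerate(self):
        res = wr.bootstrap_engine([3.0], seed=0, n_resamples=100)
        assert res.degenerate
        assert res.ci == (3.0, 3.0)

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal(16)
        a = wr.bootstrap_engine(x, seed=9, n_resamples=500)
        b = wr.bootstrap_engine(x, seed=9, n_resamples=500)
        assert np.array_equal(a.distribution, b.distribution)
        assert a.ci == b.ci

    def test_bca_interval_matches_scipy(self, rng):
        # independent cross-check against scipy's BCa implementation
        from scipy.stats import bootstrap as scipy_bootstrap
        x = rng.standard_normal(16) + 0.5
        ours = wr.bootstrap_engine(x, seed=3, n_resamples=4000)
        ref = scipy_bootstrap((x,), np.mean, n_resamples=4000,
                              confidence_level=0.95, method="BCa",
                              random_state=np.random.default_rng(3))
        lo, hi = ref.confidence_interval
        width = hi - lo
        assert ours.ci[0] == pytest.approx(lo, abs=0.1 * width)
        assert ours.ci[1] == pytest.approx(hi, abs=0.1 * width)

    def test_bca_coverage_of_normal_mean(self):
        # coverage oracle over normal(μ=2, σ=3) samples: at n=16 the BCa
        # interval undercovers somewhat (the method's known small-sample
        # behaviour — scipy's BCa measures ~90% here too); at n=100 the
        # coverage reaches the nominal 95% within Monte-Carlo error
        rng = np.random.default_rng(7)
        mu = 2.0
        for n, lo_band, hi_band in ((16, 0.89, 0.96), (100, 0.93, 0.97)):
            covered = 0
            n_rep = 500
            for i in range(n_rep):
                x = rng.normal(mu, 3.0, n)
                res = wr.bootstrap_engine(x, seed=i, n_resamples=1000)
                covered += res.ci[0] <= mu <= res.ci[1]
            assert lo_band <= covered / n_rep <= hi_band


class TestSpectralPeakTest:
    def test_floor_p_value(self):
        res = wr.spectral_peak_test(np.full(16, 5.0) +
                                    np.arange(16) * 0.01, seed=0)
        assert res.p_value == pytest.approx(1 / 10001)
        assert res.n_resamples == 10000

    def test_ceiling_p_value(self):
        res = wr.spectral_peak_test(-np.full(16, 5.0) -
                                    np.arange(16) * 0.01, seed=0)
        assert res.p_value == pytest.approx(1.0)


class TestPowerDifferenceTest:
    def test_identical_conditions_p_near_one(self, rng):
        x = rng.standard_normal(16)
        res = wr.power_difference_test(x, x, seed=1)
        assert res.p_value > 0.9

    def test_symmetry_under_swap(self, rng):
        a, b = rng.standard_normal(16), rng.standard_normal(16)
        p_ab = wr.power_difference_test(a, b, seed=2).p_value
        p_ba = wr.power_difference_test(b, a, seed=2).p_value
        assert p_ab == p_ba

    def test_unpaired_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="equal"):
            wr.power_difference_test(rng.standard_normal(16),
                                     rng.standard_normal(15))

    def test_detects_threefold_power_difference(self):
        # power-calibration oracle: 3x power difference at n=16 detected in
        # at least 90% of replicates at the SNR of the grand-average stage
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            base = np.abs(rng.normal(3.0, 1.0, 16))
            a = base * 3 + rng.normal(0, 1.0, 16)
            b = base + rng.normal(0, 1.0, 16)
            p = wr.power_difference_test(a, b, n_resamples=1000, seed=i).p_value
            hits += p < 0.05
        assert hits / n_rep >= 0.90


class TestCrossExperimentTest:
    def test_identical_groups_p_near_one(self, rng):
        x = rng.standard_normal(16)
        res = wr.cross_experiment_test(x, x.copy(), seed=3)
        assert res.p_value > 0.5

    def test_large_shift_hits_floor(self, rng):
        a = rng.standard_normal(16)
        res = wr.cross_experiment_test(a + 100.0, a, seed=4)
        assert res.p_value == pytest.approx(1 / 10001)

    def test_percentile_method_available(self, rng):
        a, b = rng.standard_normal(16), rng.standard_normal(20)
        res = wr.cross_experiment_test(a, b, seed=5, method="percentile")
        assert 0 < res.p_value <= 1


class TestPhaseDifferenceCI:
    def test_degenerate_resamples_zero_width(self):
        lo, hi = wr.phase_difference_ci(np.full(1000, 41.0))
        assert lo == pytest.approx(41.0)
        assert hi == pytest.approx(41.0)

    def test_full_coverage_uniform_is_full_circle(self, rng):
        lo, hi = wr.phase_difference_ci(rng.uniform(-180, 180, 1000),
                                        coverage=100.0)
        arc = (hi - lo) % 360
        assert arc > 350 or arc == 0

    def test_wraparound_arc(self):
        angles = np.concatenate([np.full(50, 175.0), np.full(50, -175.0)])
        lo, hi = wr.phase_difference_ci(angles, coverage=95.0)
        assert lo == pytest.approx(175.0)
        assert hi == pytest.approx(-175.0)

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            wr.phase_difference_ci([0.0], coverage=0.0)

    def test_von_mises_coverage(self):
        # coverage oracle: the 95% shortest arc over resampled circular
        # means should cover the true direction ~95% of the time
        rng = np.random.default_rng(17)
        mu, hits, n_rep = 30.0, 0, 300
        for i in range(n_rep):
            phases = np.degrees(rng.vonmises(np.radians(mu), 4.0, 16))
            idx = rng.integers(0, 16, (2000, 16))
            z = np.exp(1j * np.radians(phases))
            boot = np.degrees(np.angle(np.mean(z[idx], axis=1)))
            lo, hi = wr.phase_difference_ci(boot, coverage=95.0)
            arc = (hi - lo) % 360
            hits += (wrap_degrees(mu - lo) % 360) <= arc
        assert hits / n_rep == pytest.approx(0.95, abs=0.04)


class TestPhaseCoherence:
    def test_identical_phases_floor_p(self):
        res = wr.phase_coherence_test(np.full(16, 25.0), seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 10001)

    def test_antipodal_pair_incoherent(self):
        res = wr.phase_coherence_test([10.0, -170.0], seed=1)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(23)
        ps = [wr.phase_coherence_test(rng.uniform(-180, 180, 16),
                                      n_null=500, seed=i).p_value
              for i in range(200)]
        ps = np.array(ps)
        assert abs((ps < 0.5).mean() - 0.5) < 0.1
        assert abs(ps.mean() - 0.5) < 0.08


class TestFDR:
    def brute_force_bh(self, p):
        # independent step-up oracle
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * m / rank)
            adj[i] = val
            prev = val
        return adj

    def test_single_p_unchanged(self):
        assert wr.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_fixed_point(self):
        assert np.allclose(wr.fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_matches_brute_force_on_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert np.allclose(wr.fdr_adjust(p), self.brute_force_bh(p))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_and_preserves_order(self, p):
        adj = wr.fdr_adjust(p)
        assert np.allclose(adj, self.brute_force_bh(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            wr.fdr_adjust([0.0, 0.5])


class TestClusterPermutation:
    def test_no_difference_no_clusters(self, rng):
        a = rng.standard_normal((12, 80))
        res = wr.cluster_permutation_test(a, a.copy(), n_permutations=200,
                                          seed=0)
        assert res.clusters == []

    def test_detects_injected_interval(self):
        # injected difference confined to 0.30-0.50 s at high SNR
        rng = np.random.default_rng(31)
        fs, n, n_t = 128.0, 16, 109
        t = np.arange(n_t) / fs
        bump = np.where((t >= 0.30) & (t <= 0.50), 2.0, 0.0)
        a = rng.standard_normal((n, n_t)) + bump
        b = rng.standard_normal((n, n_t))
        res = wr.cluster_permutation_test(a, b, n_permutations=500, seed=1,
                                          sampling_rate=fs)
        sig = [c for c, p in zip(res.clusters, res.cluster_p) if p < 0.05]
        assert sig, "no significant cluster found"
        lo = min(c[0] for c in sig)
        hi = max(c[1] for c in sig)
        assert lo < 0.50 and hi > 0.30      # overlaps the injected window

    def test_deterministic_given_seed(self, rng):
        a = rng.standard_normal((10, 60))
        b = rng.standard_normal((10, 60))
        r1 = wr.cluster_permutation_test(a, b, n_permutations=200, seed=5)
        r2 = wr.cluster_permutation_test(a, b, n_permutations=200, seed=5)
        assert r1.cluster_p == r2.cluster_p

    def test_too_few_participants_rejected(self, rng):
        with pytest.raises(ValueError, match="participants"):
            wr.cluster_permutation_test(rng.standard_normal((1, 50)),
                                        rng.standard_normal((1, 50)))


class TestPairedEffectSize:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            wr.paired_effect_size([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])

    def test_d_recovery(self):
        # Monte-Carlo oracle: paired normals with true d = 1.0, n = 16
        rng = np.random.default_rng(41)
        estimates = []
        for _ in range(300):
            diff = rng.normal(1.0, 1.0, 16)
            d, _ = wr.paired_effect_size(diff, np.zeros(16))
            estimates.append(d)
        assert abs(np.mean(estimates) - 1.0) < 0.15

    def test_null_power_equals_alpha_at_zero_effect(self):
        # a sign-symmetric difference sample has mean exactly 0, so d = 0
        # and the achieved power collapses to the test size α
        diff = np.concatenate([np.arange(1, 9.0), -np.arange(1, 9.0)])
        d, power = wr.paired_effect_size(diff, np.zeros(16))
        assert d == 0.0
        assert power == pytest.approx(0.05, abs=1e-6)

    def test_large_effect_high_power(self):
        d, power = wr.paired_effect_size(
            np.arange(16) * 0.1 + 2.0, np.zeros(16))
        assert power > 0.99
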