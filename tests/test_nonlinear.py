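import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insdyn.nonlinear_dynamics import (
    ChaosConfig,
    chaos01,
    cluster_chaos_mi,
    doane_bins,
    estimate_mi,
    mi_bifurcation,
    permutation_entropy,
    quadratic_extrapolate,
    stochasticity_gate,
)
from insdyn.synthetic_data import gen_dynamics_series, gen_regime_features


@pytest.fixture(scope="module")
def sine():
    return gen_dynamics_series("sine", 5000, {"freq_hz": 5.0, "rate_hz": 1526.0})


@pytest.fixture(scope="module")
def logistic():
    return gen_dynamics_series("logistic", 5000, {"r": 4.0, "x0": 0.2})


class TestChaos01:
    def test_periodic_low_kc(self, sine):
        res = chaos01(sine, ChaosConfig(seed=0))
        assert res.kc <= 0.2

    def test_logistic_high_kc(self, logistic):
        res = chaos01(logistic, ChaosConfig(seed=0))
        assert res.kc >= 0.9

    def test_seed_determinism(self, logistic):
        a = chaos01(logistic, ChaosConfig(seed=3))
        b = chaos01(logistic, ChaosConfig(seed=3))
        assert a.kc == b.kc
        np.testing.assert_array_equal(a.k_per_c, b.k_per_c)

    def test_constant_degenerate(self):
        res = chaos01(np.full(1000, 2.0), ChaosConfig(seed=0))
        assert res.verdict == "degenerate"
        assert np.isnan(res.kc)

    def test_amplitude_invariance_exact(self, logistic):
        # internal standardization makes Kc exactly scale-invariant
        a = chaos01(logistic, ChaosConfig(seed=5))
        b = chaos01(1000.0 * logistic, ChaosConfig(seed=5))
        assert a.kc == pytest.approx(b.kc, abs=1e-12)

    def test_sine_below_logistic_across_seeds(self, sine, logistic):
        wins = sum(
            chaos01(sine, ChaosConfig(seed=s)).kc < chaos01(logistic, ChaosConfig(seed=s)).kc
            for s in range(20)
        )
        assert wins == 20

    def test_kc_clipped_raw_retained(self, sine):
        res = chaos01(sine, ChaosConfig(seed=1))
        assert 0.0 <= res.kc <= 1.0
        assert res.kc_raw <= res.kc + 1e-12

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            chaos01(np.random.default_rng(0).standard_normal(100))

    def test_nonfinite_rejected(self):
        x = np.ones(1000)
        x[10] = np.nan
        with pytest.raises(ValueError, match="finite"):
            chaos01(x)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ChaosConfig(n0_fraction=1.5)
        with pytest.raises(ValueError):
            ChaosConfig(sigma=-1.0)

    def test_msd_profile_matches_bruteforce(self, logistic):
        # FFT displacement profile equals the direct O(N^2) computation
        from insdyn.nonlinear_dynamics import _msd_profile

        z = np.cumsum(logistic[:800] - logistic[:800].mean())
        n0 = 40
        fast = _msd_profile(z, n0)
        brute = np.array(
            [np.mean((z[n:] - z[:-n]) ** 2) for n in range(1, n0 + 1)]
        )
        np.testing.assert_allclose(fast, brute, rtol=1e-9, atol=1e-9)


class TestStochasticityGate:
    def test_white_noise_stochastic(self):
        x = np.random.default_rng(0).standard_normal(5000)
        assert stochasticity_gate(x, seed=0) == "stochastic"

    def test_logistic_deterministic(self, logistic):
        assert stochasticity_gate(logistic, seed=0) == "deterministic"

    def test_sine_deterministic(self, sine):
        assert stochasticity_gate(sine, seed=0) == "deterministic"

    def test_constant_degenerate(self):
        assert stochasticity_gate(np.full(1000, 1.0), seed=0) == "degenerate"

    def test_short_warns(self):
        x = np.random.default_rng(1).standard_normal(600)
        with pytest.warns(UserWarning, match="length"):
            stochasticity_gate(x, m=5, seed=0)

    def test_pe_bounds_and_extremes(self, logistic):
        h_noise = permutation_entropy(np.random.default_rng(2).standard_normal(5000))
        h_logi = permutation_entropy(logistic)
        assert 0.0 <= h_logi < h_noise <= 1.0
        assert h_noise > 0.99


class TestMutualInformation:
    def test_quadratic_extrapolation_exact(self):
        # I(N) = 1 + 10/N + 100/N^2 at N = 100, 50, 25 solves back exactly
        ns = [100, 50, 25]
        ivals = [1 + 10 / n + 100 / n**2 for n in ns]
        i_true, a, b = quadratic_extrapolate(ns, ivals)
        assert i_true == pytest.approx(1.0, abs=1e-9)
        assert a == pytest.approx(10.0, abs=1e-7)
        assert b == pytest.approx(100.0, abs=1e-6)

    def test_null_mi_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for rep in range(20):
            r = rng.standard_normal(200)
            s = np.repeat(np.arange(4), 50)
            vals.append(estimate_mi(r, s, seed=rep).i_corrected)
        assert abs(np.mean(vals)) < 0.05

    def test_four_disjoint_clusters_two_bits(self):
        rng = np.random.default_rng(1)
        r = np.concatenate([rng.normal(10 * k, 0.1, 50) for k in range(4)])
        s = np.repeat(np.arange(4), 50)
        mi = estimate_mi(r, s, seed=0)
        assert mi.i_corrected == pytest.approx(2.0, abs=0.1)

    def test_raw_nonnegative_random_data(self):
        rng = np.random.default_rng(2)
        for rep in range(10):
            r = rng.standard_normal(80)
            s = rng.integers(0, 3, 80)
            mi = estimate_mi(r, s, seed=rep)
            assert mi.i_raw >= 0.0
            assert mi.i_half >= 0.0
            assert mi.i_quarter >= 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        r = rng.standard_normal(120)
        s = np.repeat(np.arange(3), 40)
        perm = rng.permutation(120)
        a = estimate_mi(r, s, seed=0)
        b = estimate_mi(r[perm], s[perm], seed=0)
        assert a.i_raw == pytest.approx(b.i_raw, abs=1e-12)

    def test_small_class_excluded(self):
        r = np.concatenate([np.zeros(20), np.ones(20), np.full(3, 2.0)])
        s = np.concatenate([np.zeros(20), np.ones(20), np.full(3, 2.0)])
        with pytest.warns(UserWarning, match="excluding"):
            mi = estimate_mi(r, s, seed=0)
        assert mi.n == 40

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            estimate_mi(np.zeros(20), np.zeros(20))

    def test_extrapolate_needs_three(self):
        with pytest.raises(ValueError):
            quadratic_extrapolate([100, 50], [1.0, 1.1])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_doane_reasonable(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        assert 5 <= doane_bins(x) <= 30


class TestClustering:
    def test_two_masses_perfect(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0.1, 0.01, (30, 2)), rng.normal(0.9, 0.01, (30, 2))])
        res = cluster_chaos_mi(pts, seed=0)
        assert res.k == 2
        assert not res.no_structure
        labels = res.labels
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1

    def test_default_regime_features_k2(self):
        pts, _ = gen_regime_features()
        assert cluster_chaos_mi(pts, seed=0).k == 2

    def test_three_masses_k3(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [rng.normal(c, 0.02, (30, 2)) for c in ((0.1, 0.1), (0.5, 0.9), (0.9, 0.2))]
        )
        assert cluster_chaos_mi(pts, seed=0).k == 3

    def test_single_blob_flagged(self):
        pts = np.random.default_rng(2).normal(0.5, 0.05, (300, 2))
        assert cluster_chaos_mi(pts, seed=0).no_structure

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="too few"):
            cluster_chaos_mi(np.zeros((8, 2)))

    def test_bifurcation_between_centers(self):
        pts, labels = gen_regime_features()
        res = cluster_chaos_mi(pts, seed=0)
        split = mi_bifurcation(pts, res.labels)
        mi_means = sorted(pts[res.labels == g, 0].mean() for g in np.unique(res.labels))
        assert mi_means[0] < split < mi_means[-1]
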