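import numpy as np
import pandas as pd
import pytest

from insdyn.bayes_models import (
    RegressionSpec,
    SamplerSettings,
    find_knot,
    fit_hlr,
    fit_spike_lfp_lr,
    fit_spline_sfc,
    gibbs_linear,
    hdi,
    map_estimate,
    spline_design,
    summarize_posterior,
)

FAST = SamplerSettings(chains=2, draws=1000, warmup=500, seed=0)


class TestSummaries:
    def test_standard_normal(self):
        s = np.random.default_rng(0).standard_normal((4, 50_000))
        summ = summarize_posterior({"x": s})
        p = summ.params["x"]
        assert p.map == pytest.approx(0.0, abs=0.05)
        assert p.hdi_lo == pytest.approx(-1.96, abs=0.1)
        assert p.hdi_hi == pytest.approx(1.96, abs=0.1)
        assert not p.significant  # HDI straddles 0

    def test_point_mass(self):
        s = np.full((2, 1000), 3.25)
        summ = summarize_posterior({"x": s})
        p = summ.params["x"]
        assert p.map == 3.25
        assert p.hdi_hi - p.hdi_lo == 0.0
        assert p.significant

    def test_exponential_hdi(self):
        # narrowest 95% interval of Exp(1) is (0, -ln 0.05) = (0, 2.996)
        s = np.random.default_rng(1).exponential(1.0, (4, 100_000))
        lo, hi = hdi(s)
        assert lo == pytest.approx(0.0, abs=0.01)
        assert hi == pytest.approx(2.996, abs=0.1)

    def test_hdi_narrowest_property(self):
        rng = np.random.default_rng(2)
        for draw in (rng.standard_normal(5000), rng.exponential(1, 5000), rng.beta(2, 5, 5000)):
            lo, hi = hdi(draw)
            eq_lo, eq_hi = np.quantile(draw, [0.025, 0.975])
            assert hi - lo <= eq_hi - eq_lo + 1e-9

    def test_significance_convention(self):
        pos = np.random.default_rng(3).normal(5.0, 0.5, (2, 5000))
        both = np.random.default_rng(4).normal(0.0, 1.0, (2, 5000))
        summ = summarize_posterior({"a": pos, "b": both})
        assert summ.params["a"].significant
        assert not summ.params["b"].significant

    def test_min_draws_enforced(self):
        with pytest.raises(ValueError, match="draws"):
            summarize_posterior({"x": np.zeros((1, 100))})

    def test_multimodal_flagged(self):
        rng = np.random.default_rng(5)
        s = np.concatenate([rng.normal(-4, 0.3, 3000), rng.normal(4, 0.3, 3000)])
        m, multi = map_estimate(s)
        assert multi
        assert abs(abs(m) - 4) < 0.5  # MAP sits on one of the modes


def make_dose_table(beta_e=0.087, beta_isi=0.065, beta_x=0.0, sigma=0.5, n=400,
                    n_groups=8, seed=0, group_sd=0.02):
    rng = np.random.default_rng(seed)
    E = np.exp(rng.uniform(np.log(0.5), np.log(4.0), n))
    ISI = np.exp(rng.uniform(np.log(1.0), np.log(50.0), n))
    g = rng.integers(0, n_groups, n)
    dev = rng.normal(0, group_sd, (3, n_groups))
    X = np.column_stack([np.ones(n), np.log(E), np.log(ISI), np.log(E) * np.log(ISI)])
    beta = np.array([3.0, beta_e, beta_isi, beta_x])
    y = X @ beta + dev[0, g] * X[:, 1] + dev[1, g] * X[:, 2] + dev[2, g] * X[:, 3]
    if sigma > 0:
        y = y + sigma * rng.standard_normal(n)
    return pd.DataFrame(
        {"energy_mJ": E, "isi_ms": ISI, "rms": np.exp(y), "animal": g // 4, "electrode": g % 4}
    )


class TestHLR:
    def test_recovery_within_hdi(self):
        tab = make_dose_table(seed=1)
        summ = fit_hlr(tab, RegressionSpec(settings=FAST))
        p = summ.params["beta_energy"]
        assert p.hdi_lo <= 0.087 <= p.hdi_hi

    def test_pure_noise_null(self):
        tab = make_dose_table(beta_e=0.0, beta_isi=0.0, seed=2, group_sd=0.0)
        summ = fit_hlr(tab, RegressionSpec(settings=FAST))
        for term in ("beta_energy", "beta_isi", "beta_interaction"):
            p = summ.params[term]
            assert p.hdi_lo <= 0.0 <= p.hdi_hi

    def test_noiseless_map_close(self):
        # degenerate-likelihood check on the pooled path (< 3 groups): with a
        # hierarchy, a zero-noise likelihood cannot separate population slopes
        # from group deviations, so the pooled model is the meaningful limit
        tab = make_dose_table(sigma=1e-6, seed=3, group_sd=0.0, n_groups=2)
        summ = fit_hlr(tab, RegressionSpec(settings=FAST))
        assert summ.params["beta_energy"].map == pytest.approx(0.087, abs=1e-3)
        assert summ.params["beta_isi"].map == pytest.approx(0.065, abs=1e-3)

    def test_error_term_recovered(self):
        tab = make_dose_table(sigma=0.5, seed=4, n=800)
        summ = fit_hlr(tab, RegressionSpec(settings=FAST))
        assert summ.error.map == pytest.approx(0.5, abs=0.08)

    def test_zero_energy_rows_dropped(self):
        tab = make_dose_table(seed=5, n=100)
        tab.loc[:10, "energy_mJ"] = 0.0
        summ = fit_hlr(tab, RegressionSpec(settings=FAST))  # must not raise on ln(0)
        assert np.isfinite(summ.params["beta_energy"].map)

    def test_hierarchical_reduces_to_pooled(self):
        # group-variance prior -> 0 collapses the hierarchy onto the pooled fit
        tab = make_dose_table(seed=6, group_sd=0.0, n=300)
        hier = fit_hlr(tab, RegressionSpec(settings=FAST), tau_fixed=1e-8)
        X = np.column_stack(
            [np.ones(len(tab)), np.log(tab.energy_mJ), np.log(tab.isi_ms),
             np.log(tab.energy_mJ) * np.log(tab.isi_ms)]
        )
        pooled = gibbs_linear(X, np.log(tab.rms.to_numpy()),
                              ["intercept", "beta_energy", "beta_isi", "beta_interaction"], s=FAST)
        pooled_summ = summarize_posterior(pooled, error_name="sigma")
        for term in ("beta_energy", "beta_isi"):
            assert hier.params[term].map == pytest.approx(pooled_summ.params[term].map, abs=0.01)

    def test_ppc_pvalue_sane(self):
        summ = fit_hlr(make_dose_table(seed=7), RegressionSpec(settings=FAST))
        assert 0.01 < summ.ppc_pvalue < 0.99


class TestSpikeLFP:
    def make_table(self, b1=1.8, b2=-0.047, sigma=0.1, n=300, seed=0, shuffle=False):
        rng = np.random.default_rng(seed)
        rate = np.exp(rng.uniform(np.log(5), np.log(100), n))
        isi = np.exp(rng.uniform(np.log(1), np.log(100), n))
        y = 1.0 + b1 * np.log(rate) + b2 * np.log(isi) + sigma * rng.standard_normal(n)
        if shuffle:
            rate = rng.permutation(rate)
        return pd.DataFrame({"spike_rate": rate, "isi_ms": isi, "rms": y})

    def test_positive_rate_slope(self):
        summ = fit_spike_lfp_lr(self.make_table(), settings=FAST)
        assert summ.params["beta_spikerate"].hdi_lo > 0

    def test_shuffled_null(self):
        summ = fit_spike_lfp_lr(self.make_table(sigma=1.0, shuffle=True, seed=1), settings=FAST)
        p = summ.params["beta_spikerate"]
        assert p.hdi_lo <= 0.0 <= p.hdi_hi

    def test_sign_pattern_rate_up_isi_down(self):
        summ = fit_spike_lfp_lr(self.make_table(seed=2), settings=FAST)
        assert summ.params["beta_spikerate"].significant
        assert summ.params["beta_spikerate"].map > 0
        assert summ.params["beta_isi"].significant
        assert summ.params["beta_isi"].map < 0

    def test_zero_rates_rejected(self):
        tab = pd.DataFrame({"spike_rate": [0.0, 0.0], "isi_ms": [5.0, 5.0], "rms": [1.0, 1.0]})
        with pytest.raises(ValueError, match="positive spike rate"):
            fit_spike_lfp_lr(tab, settings=FAST)


ENERGIES = np.array([0.05, 0.075, 0.1, 0.125, 0.15, 0.2, 0.3, 0.5, 1.0, 2.0, 4.0])


def step_sfc(energies, knot, jump=0.08, slope=0.15):
    return np.where(
        energies < knot, 0.2, 0.2 + jump + slope * (np.log(energies) - np.log(knot))
    )


class TestKnot:
    def test_break_at_0p15(self):
        assert find_knot(ENERGIES, step_sfc(ENERGIES, 0.15)) == pytest.approx(0.15)

    def test_break_at_0p125(self):
        assert find_knot(ENERGIES, step_sfc(ENERGIES, 0.125)) == pytest.approx(0.125)

    def test_linear_no_knot(self):
        assert find_knot(ENERGIES, 0.1 + 0.05 * np.log(ENERGIES)) is None

    def test_too_few_points(self):
        with pytest.raises(ValueError, match=">= 8"):
            find_knot(ENERGIES[:5], step_sfc(ENERGIES[:5], 0.15))


class TestSplineFit:
    def make_table(self, knot=0.15, slope_above=0.15, slope_below=0.0, noise=0.02,
                   reps=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for e in ENERGIES:
            x = np.log(e) - np.log(knot)
            base = 0.2 + (slope_below * x if e < knot else slope_above * x)
            for _ in range(reps):
                rows.append({"energy_mJ": e, "sfc": base + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_domains_partition(self):
        X = spline_design(ENERGIES, 0.15)
        below = ENERGIES < 0.15
        assert np.all(X[below, 2] == 0)
        assert np.all(X[~below, 1] == 0)
        assert np.all(X[below, 1] != 0)

    def test_flat_below_rising_above(self):
        summ = fit_spline_sfc(self.make_table(), 0.15, settings=FAST)
        below, above = summ.params["beta_below"], summ.params["beta_above"]
        assert below.hdi_lo <= 0.0 <= below.hdi_hi
        assert above.hdi_lo > 0
        assert above.map == pytest.approx(0.15, abs=0.03)

    def test_globally_flat_both_null(self):
        summ = fit_spline_sfc(self.make_table(slope_above=0.0, noise=0.05, seed=1), 0.15,
                              settings=FAST)
        for term in ("beta_below", "beta_above"):
            p = summ.params[term]
            assert p.hdi_lo <= 0.0 <= p.hdi_hi

    def test_noiseless_two_segment_recovery(self):
        summ = fit_spline_sfc(
            self.make_table(slope_below=0.04, slope_above=0.2, noise=1e-7, seed=2),
            0.15, settings=FAST,
        )
        assert summ.params["beta_below"].map == pytest.approx(0.04, abs=1e-2)
        assert summ.params["beta_above"].map == pytest.approx(0.2, abs=1e-2)

    def test_sparse_segment_noted(self):
        tab = self.make_table(reps=1)
        summ = fit_spline_sfc(tab[tab.energy_mJ >= 0.125], 0.15, settings=FAST)
        assert any("below" in n for n in summ.notes)
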