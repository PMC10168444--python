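"""Release statistics: n_T, rates, power-law fits, PPR, asynchronous counts."""

import numpy as np
import pytest

from synclamp import (
    asynchronous_count,
    cumulative_release,
    fit_power_exponent,
    peak_release_rate,
    per_ap_efficacy,
    release_rate,
    summarize_release,
    tripartite_free_probability,
)
from conftest import make_record


class TestCumulativeRelease:
    def test_single_event_step(self):
        rec = make_record([1.0], n_simulations=4, t_end=10.0)
        grid = np.array([0.5, 1.0, 2.0, 10.0])
        assert cumulative_release(rec, grid).tolist() == [0.0, 0.25, 0.25, 0.25]

    def test_empty_record_zero_curve(self):
        rec = make_record([], n_simulations=10, t_end=5.0)
        assert np.all(cumulative_release(rec, np.array([1.0, 2.0])) == 0.0)

    def test_limit_is_event_fraction(self):
        rec = make_record([0.1, 0.2, 3.0], n_simulations=6, t_end=5.0)
        assert cumulative_release(rec, np.array([5.0]))[0] == 0.5


class TestReleaseRate:
    def test_poisson_plateau_recovered(self, rng):
        """A homogeneous Poisson event stream has a flat rate ~ lambda."""
        lam, t_end, n_sims = 0.2, 50.0, 400
        counts = rng.poisson(lam * t_end, n_sims)
        times = np.concatenate(
            [rng.uniform(0, t_end, c) for c in counts])
        sim_ids = np.concatenate(
            [np.full(c, i) for i, c in enumerate(counts)])
        rec = make_record(np.sort(times), n_sims, t_end,
                          sim_ids=sim_ids[np.argsort(times)])
        est = release_rate(rec, binning="adaptive", events_per_bin=100)
        se = lam / np.sqrt(100)
        assert np.all(np.abs(est.raw_rate - lam) < 4 * se)

    def test_unsmoothed_rates_integrate_to_nT(self):
        rec = make_record([0.3, 0.5, 1.7, 4.2, 9.9], 10, 10.0)
        est = release_rate(rec, binning="fixed", bin_width=0.25)
        assert est.integral() == pytest.approx(0.5, abs=1e-12)

    def test_empty_record_fixed_bins_zero(self):
        rec = make_record([], 10, 10.0)
        est = release_rate(rec, binning="fixed")
        assert np.all(est.rate == 0.0)

    def test_adaptive_fallback_warns(self):
        rec = make_record([1.0, 2.0], 10, 10.0)
        with pytest.warns(UserWarning, match="falling back"):
            release_rate(rec, binning="adaptive", events_per_bin=50)


class TestPeakRate:
    def test_monotone_decay_peaks_first_bin(self, rng):
        times = rng.exponential(1.0, 2000)
        rec = make_record(np.sort(times[times < 10]), 2000, 10.0)
        est = release_rate(rec, binning="fixed", bin_width=0.5,
                           smooth_window=1)
        peak, t_peak = peak_release_rate(est)
        assert t_peak == est.t[0]

    def test_window_restriction(self):
        rec = make_record([0.1, 0.2, 5.0, 5.1, 5.2, 5.3], 10, 10.0)
        est = release_rate(rec, binning="fixed", bin_width=1.0,
                           smooth_window=1)
        _, t_all = peak_release_rate(est)
        _, t_early = peak_release_rate(est, window=2.0)
        assert t_all > 2.0 > t_early


class TestPowerExponent:
    def test_exact_power_law(self):
        ca = np.array([2.0, 4.0, 8.0, 16.0])
        assert fit_power_exponent(ca, ca**4) == pytest.approx(4.0)

    def test_two_point_slope_closed_form(self):
        assert fit_power_exponent([4.0, 8.0], [1.0, 8.0]) == pytest.approx(
            np.log2(8.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_power_exponent([4.0, 8.0], [0.0, 1.0])


class TestPerApEfficacy:
    def test_partition_conservation(self, rng):
        """Sum of per-AP efficacies plus the asynchronous tail recovers the
        total cumulative release, for any window partition."""
        times = np.sort(rng.uniform(0, 100, 500))
        rec = make_record(times, 1000, 100.0)
        ap = [10.0, 20.0, 30.0]
        eff = per_ap_efficacy(rec, ap, final_window=5.0)
        before = np.sum(times < 10.0) / 1000
        n_async = asynchronous_count(rec, 35.0, 100.0)
        total = cumulative_release(rec, np.array([100.0]))[0]
        assert eff["n_T"].sum() + before + n_async == pytest.approx(total)

    def test_memoryless_system_ppr_one(self, rng):
        """Identical independent windows (instant reset) give PPR ~ 1."""
        n = 20000
        t1 = 10.0 + rng.exponential(0.5, n)
        t2 = 60.0 + rng.exponential(0.5, n)
        keep1, keep2 = rng.random(n) < 0.2, rng.random(n) < 0.2
        times = np.sort(np.concatenate([t1[keep1], t2[keep2]]))
        rec = make_record(times, n, 110.0)
        eff = per_ap_efficacy(rec, [10.0, 60.0], window_width=20.0)
        assert eff["PPR"] == pytest.approx(1.0, abs=0.05)

    def test_depletion_gives_depression(self):
        """Without replenishment p_v(2) <= 1 - p_v(1): high first-pulse
        release forces PPR < 1."""
        n = 1000
        t1 = np.linspace(10.01, 10.5, 600)          # 60% release at AP1
        t2 = np.linspace(30.01, 30.5, 240)          # 60% of the remaining 40%
        rec = make_record(np.concatenate([t1, t2]), n, 40.0)
        eff = per_ap_efficacy(rec, [10.0, 30.0])
        assert eff["PPR"] == pytest.approx(0.4, abs=1e-9)

    def test_no_first_release_gives_nan(self):
        rec = make_record([31.0], 100, 40.0)
        eff = per_ap_efficacy(rec, [10.0, 30.0])
        assert np.isnan(eff["PPR"])

    def test_window_width_exceeding_isi_rejected(self):
        rec = make_record([1.0], 10, 40.0)
        with pytest.raises(ValueError):
            per_ap_efficacy(rec, [10.0, 20.0], window_width=15.0)


class TestAsynchronousCount:
    def test_no_tail_events(self):
        rec = make_record([1.0, 2.0], 10, 50.0)
        assert asynchronous_count(rec, 10.0) == 0.0

    def test_poisson_tail_rate(self, rng):
        lam, n = 0.05, 2000
        times = np.sort(rng.uniform(0, 100, rng.poisson(lam * 100 * n)))
        rec = make_record(times, n, 100.0)
        expected = lam * 60.0
        got = asynchronous_count(rec, 40.0, 100.0)
        se = np.sqrt(expected / n)
        assert abs(got - expected) < 3 * se


class TestTripartiteProbability:
    def test_requires_snapshots(self):
        rec = make_record([1.0], 10, 10.0)
        with pytest.raises(ValueError, match="snapshot"):
            tripartite_free_probability(rec, 5.0)


class TestSummarize:
    def test_bundle_consistency(self, rng):
        times = np.sort(rng.exponential(2.0, 800))
        rec = make_record(times[times < 20], 1000, 20.0)
        stats = summarize_release(rec, async_start=10.0)
        assert stats.n_T[-1] == pytest.approx(
            cumulative_release(rec, np.array([20.0]))[0])
        assert stats.peak_rate >= 0
        assert stats.n_async == asynchronous_count(rec, 10.0)
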