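"""Stochastic engine: exactness, determinism, replenishment, fast path."""

import numpy as np
import pytest
from scipy import stats

from synclamp import (
    DEFAULT_BARRIER,
    FusionBarrier,
    SimulationProtocol,
    SYT1,
    cumulative_release,
    make_egta_jump,
    make_step,
    preset,
    record_free_snare_trajectory,
    simulate_ensemble,
    simulate_vesicle,
    solve_lumped_roi_master,
)
from synclamp.fastpath import step_fusion_times
from synclamp.kinetics import c2_generator
from synclamp.ssa import FUSION, REPLENISH


def constant_hazard_barrier(lam: float) -> FusionBarrier:
    """Barrier whose resting fusion rate is ``lam`` ms^-1, ~flat in n."""
    return FusionBarrier(E0=np.log(2.17e6 / lam), dE=1e-9, A=2.17e9)


class TestSingleVesicle:
    def test_event_tuple_shape(self):
        proto = SimulationProtocol(trace=make_step(16.0, 10.0),
                                   n_simulations=1, rng_seed=4)
        events = simulate_vesicle(preset("SYT1P"), proto, 4)
        assert all(e[0] in ("fusion", "replenish") for e in events)
        assert len(events) <= 1  # no replenishment: at most one fusion

    def test_t_end_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            SimulationProtocol(trace=make_step(16.0, 5.0), t_end=10.0)


class TestExactness:
    def test_resting_fusion_probability(self):
        """At zero Ca2+ the only channel is R(0); p = 1 - exp(-R(0) t)."""
        proto = SimulationProtocol(trace=make_step(0.0, 10.0),
                                   n_simulations=200_000, rng_seed=5)
        rec = simulate_ensemble(preset("SYT1P"), proto)
        expected = 1.0 - np.exp(-DEFAULT_BARRIER.rate(0) * 10.0)
        n_exp = expected * proto.n_simulations
        assert abs(rec.n_fusions - n_exp) < 3.0 * np.sqrt(n_exp)

    def test_waiting_times_exponential(self):
        """With a constant hazard the fusion times are exactly exponential."""
        lam = 0.5
        proto = SimulationProtocol(trace=make_step(0.0, 80.0),
                                   n_simulations=4000, rng_seed=6,
                                   barrier=constant_hazard_barrier(lam))
        rec = simulate_ensemble(preset("SYT1P", n_snare=1), proto)
        # truncation at t_end is negligible: exp(-40) left
        res = stats.kstest(rec.fusion_times, "expon", args=(0.0, 1.0 / lam))
        assert res.pvalue > 1e-3

    def test_matches_lumped_master_equation(self):
        """Fusion-time law under a 16 uM step agrees with the exact oracle."""
        tr = make_step(16.0, 10.0)
        proto = SimulationProtocol(trace=tr, n_simulations=3000, rng_seed=7)
        rec = simulate_ensemble(preset("SYT1P"), proto)
        sol = solve_lumped_roi_master(preset("SYT1P"), tr,
                                      t_eval=np.linspace(0.0, 10.0, 801))
        cdf = lambda t: np.interp(t, sol.t, sol.n_T) / sol.n_T[-1]
        times = rec.fusion_times
        res = stats.kstest(times, cdf)
        # all sims fuse by 10 ms at 16 uM (oracle: n_T = 0.99996)
        assert res.pvalue > 1e-3

    def test_nfree_at_fusion_within_bounds(self):
        proto = SimulationProtocol(trace=make_step(16.0, 10.0),
                                   n_simulations=500, rng_seed=8,
                                   record_nfree_at_fusion=True)
        rec = simulate_ensemble(preset("SYT1P"), proto)
        nf = rec.nfree_at_fusion()
        assert nf.size == rec.n_fusions
        assert np.all((nf >= 0) & (nf <= 6))


class TestDeterminism:
    def test_bitwise_reproducibility(self):
        proto = SimulationProtocol(trace=make_step(8.0, 10.0),
                                   n_simulations=500, rng_seed=42)
        a = simulate_ensemble(preset("SYT1P"), proto)
        b = simulate_ensemble(preset("SYT1P"), proto)
        assert np.array_equal(a.t_ms, b.t_ms)
        assert np.array_equal(a.sim_id, b.sim_id)
        assert np.array_equal(a.event_type, b.event_type)

    def test_seed_changes_output(self):
        p1 = SimulationProtocol(trace=make_step(8.0, 10.0),
                                n_simulations=500, rng_seed=1)
        p2 = SimulationProtocol(trace=make_step(8.0, 10.0),
                                n_simulations=500, rng_seed=2)
        a = simulate_ensemble(preset("SYT1P"), p1)
        b = simulate_ensemble(preset("SYT1P"), p2)
        assert not np.array_equal(a.t_ms, b.t_ms)


class TestRecordInvariants:
    def test_at_most_one_event_without_replenishment(self):
        proto = SimulationProtocol(trace=make_step(16.0, 10.0),
                                   n_simulations=2000, rng_seed=9)
        rec = simulate_ensemble(preset("SYT1P"), proto)
        _, counts = np.unique(rec.sim_id, return_counts=True)
        assert counts.max() == 1
        assert np.all((rec.t_ms >= 0) & (rec.t_ms <= 10.0))

    def test_cumulative_release_monotone_and_bounded(self):
        proto = SimulationProtocol(trace=make_step(8.0, 10.0),
                                   n_simulations=2000, rng_seed=10)
        rec = simulate_ensemble(preset("SYT1P"), proto)
        grid = np.linspace(0.01, 10.0, 300)
        nT = cumulative_release(rec, grid)
        assert np.all(np.diff(nT) >= 0)
        assert nT[-1] <= 1.0

    def test_csv_round_trip(self, tmp_path):
        proto = SimulationProtocol(trace=make_step(16.0, 10.0),
                                   n_simulations=200, rng_seed=11,
                                   record_nfree_at_fusion=True)
        rec = simulate_ensemble(preset("SYT1P"), proto)
        path = tmp_path / "events.csv"
        rec.to_csv(path)
        back = type(rec).from_csv(path)
        assert np.allclose(back.t_ms, rec.t_ms)
        assert back.total_simulations == rec.total_simulations


class TestReplenishment:
    def test_event_alternation_and_rate(self):
        """With an ~instant refusing barrier, sites cycle at the
        refractory + replenishment timescale: ~t_end/(t_ref + 1/k_rep)
        fusions per site."""
        lam = 1e3
        proto = SimulationProtocol(
            trace=make_step(0.0, 1000.0), n_simulations=400, rng_seed=12,
            replenishment_enabled=True, t_refractory=2.5, k_rep=0.02,
            barrier=constant_hazard_barrier(lam),
        )
        rec = simulate_ensemble(preset("SYT1P"), proto)
        cycle = 1.0 / lam + 2.5 + 50.0
        n_exp = (1.0 + 1000.0 / cycle) * 400  # immediate first fusion + renewals
        assert abs(rec.n_fusions - n_exp) < 4.0 * np.sqrt(n_exp)
        for sim in np.unique(rec.sim_id)[:20]:
            mask = rec.sim_id == sim
            assert np.all(np.diff(rec.t_ms[mask]) > 0)
            kinds = rec.event_type[mask]
            assert np.all(kinds[:-1:2] == FUSION)
            assert np.all(kinds[1::2] == REPLENISH)

    def test_stop_events_mode(self):
        proto = SimulationProtocol(trace=make_step(16.0, 10.0),
                                   n_simulations=None, stop_events=50,
                                   rng_seed=13)
        rec = simulate_ensemble(preset("SYT1P"), proto)
        assert rec.n_fusions >= 50
        assert rec.complete

    def test_stop_events_unreachable_flags_partial(self):
        proto = SimulationProtocol(trace=make_step(0.0, 1.0),
                                   n_simulations=50, stop_events=10,
                                   rng_seed=14)
        with pytest.warns(UserWarning, match="not reached"):
            rec = simulate_ensemble(preset("SYT1P"), proto)
        assert not rec.complete


class TestSnapshots:
    def test_initial_state_all_clamped(self):
        proto = SimulationProtocol(trace=make_step(16.0, 5.0),
                                   n_simulations=300, rng_seed=15)
        traj = record_free_snare_trajectory(preset("SYT1P"), proto)
        assert traj.table["mean_nfree"].iloc[0] == 0.0
        assert traj.table["n_docked"].iloc[0] == 300

    def test_stochastic_stopped_flow_matches_master_equation(self):
        """Engine-level cross-check: P(S2M)(t) of a single clamp domain
        tracks the deterministic four-state master equation through an
        equilibrate-then-jump Ca2+ protocol, within binomial error."""
        tr = make_egta_jump(150.0, 2.0, 10.0)
        barrier = FusionBarrier(E0=80.0, dE=1e-9, A=2.17e9)  # fusion off
        proto = SimulationProtocol(trace=tr, n_simulations=2000, rng_seed=16,
                                   snapshot_dt=0.5, barrier=barrier)
        rec = simulate_ensemble(preset("SYT1P", n_snare=1), proto)
        snaps = rec.snapshots
        # deterministic reference, same all-S0 start
        from scipy.integrate import solve_ivp
        p0 = np.array([1.0, 0.0, 0.0, 0.0])
        Q_hi = c2_generator(SYT1, 150.0)
        Q_lo = c2_generator(SYT1, 0.0)
        first = solve_ivp(lambda t, y: Q_hi.T @ y, (0, 2), p0, rtol=1e-10,
                          atol=1e-12, dense_output=True)
        second = solve_ivp(lambda t, y: Q_lo.T @ y, (0, 8), first.y[:, -1],
                           rtol=1e-10, atol=1e-12, dense_output=True)
        for i, t in enumerate(snaps.t):
            m = (first.sol(t)[3] if t <= 2.0 else second.sol(t - 2.0)[3])
            se = np.sqrt(max(m * (1 - m), 1e-6) / 2000)
            assert abs(snaps.mean_nfree()[i] - m) < 4 * se


class TestFastPath:
    def test_matches_generic_engine(self):
        """Jitted constant-Ca kernel samples the same fusion-time law."""
        arch = preset("SYT1P")
        t_fast, nf_fast, _ = step_fusion_times(arch, 8.0, 10.0, 4000, 17)
        proto = SimulationProtocol(trace=make_step(8.0, 10.0),
                                   n_simulations=4000, rng_seed=18,
                                   record_nfree_at_fusion=True)
        rec = simulate_ensemble(arch, proto)
        res = stats.ks_2samp(t_fast, rec.fusion_times)
        assert res.pvalue > 1e-3
        assert abs(np.mean(nf_fast) - np.mean(rec.nfree_at_fusion())) < 0.15

    def test_mixed_architecture_rejected(self):
        with pytest.raises(ValueError):
            step_fusion_times(preset("MIXED_SYT7"), 8.0, 10.0, 10, 1)
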