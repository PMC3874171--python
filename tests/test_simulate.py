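import numpy as np
import pytest

from nucdyn import (
    BarrierSpec,
    KineticParams,
    LatticeState,
    calibrate_activity,
    gillespie_step,
    oscillation_amplitude,
    occupancy_profile,
    percus_occupancy,
    replay_state,
    run_ensemble,
    run_trajectory,
)
from nucdyn.simulate import derive_seeds
from nucdyn.tracks import uniform_potential

SMALL = KineticParams(k_on=1.0, k_slide=0.5, active_shift=0.5, footprint_k=6)


class TestTrajectory:
    def test_zero_horizon_empty_log(self):
        tr = uniform_potential(60, -1.0)
        log = run_trajectory(tr, SMALL, t_end=0.0, snapshot_times=[0.0], seed=1)
        assert log.n_events == 0
        assert log.snapshots[0].size == 0

    def test_same_seed_bit_identical(self):
        tr = uniform_potential(120, -1.5)
        a = run_trajectory(tr, SMALL, t_end=20.0, seed=9)
        b = run_trajectory(tr, SMALL, t_end=20.0, seed=9)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.kinds, b.kinds)
        assert np.array_equal(a.pos_after, b.pos_after)

    def test_different_seeds_differ(self):
        tr = uniform_potential(120, -1.5)
        a = run_trajectory(tr, SMALL, t_end=20.0, seed=9)
        b = run_trajectory(tr, SMALL, t_end=20.0, seed=10)
        assert not (
            a.n_events == b.n_events and np.array_equal(a.times, b.times)
        )

    def test_replay_reproduces_every_snapshot(self):
        tr = uniform_potential(200, -1.0)
        snaps = [0.0, 1.0, 5.0, 12.0, 30.0]
        log = run_trajectory(tr, SMALL, t_end=30.0, snapshot_times=snaps, seed=4)
        for t, snap in zip(snaps, log.snapshots):
            assert np.array_equal(replay_state(log, t), snap)
        assert np.array_equal(replay_state(log, 30.0), log.final_starts)

    def test_hard_core_holds_after_every_event(self):
        tr = uniform_potential(150, -2.0)
        log = run_trajectory(tr, SMALL, t_end=40.0, seed=13)
        for t in np.linspace(0, 40.0, 60):
            starts = replay_state(log, t)
            if starts.size > 1:
                assert (np.diff(starts) >= 6).all()

    def test_barrier_region_never_covered(self):
        tr = uniform_potential(400, -2.0, tss_offset=100)
        bar = BarrierSpec(kind="hard", start_j=-50, end_j=-1)
        log = run_trajectory(tr, SMALL, bar, t_end=50.0, seed=2)
        for t in np.linspace(0, 50.0, 40):
            for s in replay_state(log, t):
                assert s + 6 <= 50 or s >= 100


class TestGillespieStep:
    def test_empty_lattice_only_adsorption(self):
        tr = uniform_potential(60, -1.0)
        st = LatticeState(length_bp=60, footprint_k=6)
        rng = np.random.default_rng(0)
        new, dt, event = gillespie_step(st, tr, SMALL, rng)
        assert event[0] == "adsorb"
        assert new.n_nucleosomes == 1

    def test_lone_desorption_when_only_move(self):
        tr = uniform_potential(12, -1.0)
        p = KineticParams(k_on=0.0, k_slide=0.0, k0_off=1.0, footprint_k=6)
        st = LatticeState(length_bp=12, starts=np.array([3]), footprint_k=6)
        new, dt, event = gillespie_step(st, tr, p, np.random.default_rng(0))
        assert event == ("desorb", 3, -1)
        assert new.n_nucleosomes == 0

    def test_absorbing_state_signalled(self):
        tr = uniform_potential(12, -1.0)
        p = KineticParams(k_on=0.0, k_slide=0.0, footprint_k=6)
        st = LatticeState(length_bp=12, footprint_k=6)
        with pytest.raises(RuntimeError):
            gillespie_step(st, tr, p, np.random.default_rng(0))

    def test_event_frequencies_match_rates(self):
        """Single-step event-type frequencies reproduce the exact propensities."""
        tr = uniform_potential(20, -2.0)
        p = KineticParams(k_on=1.0, k_slide=0.7, active_shift=0.0, footprint_k=6)
        st = LatticeState(length_bp=20, starts=np.array([0, 8]), footprint_k=6)
        # eligible starts: footprint [i, i+6) clear of [0,6) and [8,14) -> {14}
        a_ads = 1.0 * 1
        a_off = 2 * 1.0 * np.exp(-2.0)
        a_slide = 0.7 * 2
        R = a_ads + a_off + a_slide
        rng = np.random.default_rng(123)
        n = 20000
        counts = {"adsorb": 0, "desorb": 0, "slide": 0}
        dts = np.empty(n)
        for m in range(n):
            _, dt, event = gillespie_step(st, tr, p, rng)
            counts[event[0]] += 1
            dts[m] = dt
        for kind, a in (("adsorb", a_ads), ("desorb", a_off), ("slide", a_slide)):
            f = counts[kind] / n
            se = np.sqrt(a / R * (1 - a / R) / n)
            assert abs(f - a / R) < 3 * se
        assert abs(dts.mean() - 1 / R) < 3 * dts.std() / np.sqrt(n)

    def test_doubling_kon_doubles_waiting_rate_on_empty_lattice(self):
        tr = uniform_potential(60, -1.0)
        st = LatticeState(length_bp=60, footprint_k=6)
        rng = np.random.default_rng(7)
        n = 4000
        mean_dt = {}
        for kon in (1.0, 2.0):
            p = KineticParams(k_on=kon, k_slide=0.0, footprint_k=6)
            mean_dt[kon] = np.mean(
                [gillespie_step(st, tr, p, rng)[1] for _ in range(n)]
            )
        assert mean_dt[1.0] / mean_dt[2.0] == pytest.approx(2.0, rel=0.1)


class TestEnsemble:
    def test_single_replica_reduces_to_trajectory(self):
        tr = uniform_potential(100, -1.0)
        ens = run_ensemble(tr, SMALL, t_end=10.0, n_replicas=1, base_seed=3)
        direct = run_trajectory(tr, SMALL, t_end=10.0, seed=int(ens.seeds[0]))
        assert np.array_equal(ens.logs[0].times, direct.times)

    def test_reproducible_summaries(self):
        tr = uniform_potential(150, -1.5)
        kwargs = dict(t_end=15.0, snapshot_times=[15.0], n_replicas=12, base_seed=5)
        a = run_ensemble(tr, SMALL, **kwargs)
        b = run_ensemble(tr, SMALL, **kwargs)
        pa = occupancy_profile(a, 15.0)
        pb = occupancy_profile(b, 15.0)
        assert np.array_equal(pa.p, pb.p)

    def test_seeds_pairwise_distinct(self):
        seeds = derive_seeds(0, 5000)
        assert len(set(seeds.tolist())) == 5000
        assert (seeds >= 0).all() and (seeds < 2**31).all()

    def test_occupancy_se_bound(self):
        tr = uniform_potential(150, -1.5)
        ens = run_ensemble(
            tr, SMALL, t_end=15.0, snapshot_times=[15.0], n_replicas=50, base_seed=5
        )
        prof = occupancy_profile(ens, 15.0)
        assert (prof.se <= 0.5 / np.sqrt(50) + 1e-12).all()

    def test_rejects_zero_replicas(self):
        tr = uniform_potential(100, -1.0)
        with pytest.raises(ValueError):
            run_ensemble(tr, SMALL, t_end=1.0, n_replicas=0)


class TestCalibration:
    def test_percus_route_roundtrip(self):
        tr = uniform_potential(2000, -7.0)
        p = KineticParams(k_on=1.0, k_slide=0.0, footprint_k=21)
        va = calibrate_activity(tr, p, target_density=0.8, tolerance=0.003)
        cov = percus_occupancy(tr, 21, active_shift=va).mean()
        assert cov == pytest.approx(0.8, abs=0.01)

    def test_simulation_route_agrees_with_percus_route(self):
        tr = uniform_potential(2000, -7.0)
        p = KineticParams(k_on=1.0, k_slide=0.0, footprint_k=21)
        va_pc = calibrate_activity(tr, p, target_density=0.75, tolerance=0.003)
        va_sim = calibrate_activity(
            tr, p, target_density=0.75, tolerance=0.01,
            method="simulate", n_replicas=16, base_seed=11,
        )
        assert va_sim == pytest.approx(va_pc, abs=0.35)

    def test_unreachable_target_reports_range(self):
        tr = uniform_potential(2000, -7.0)
        p = KineticParams(k_on=1.0, k_slide=0.0, footprint_k=21)
        with pytest.raises(ValueError, match="unreachable|calibration failed"):
            calibrate_activity(tr, p, target_density=0.999, bracket=(0.0, 3.0))


class TestFixedNucleosomeBarrierDynamics:
    def test_fixed_nucleosome_creates_statistical_positioning(self):
        """A lone immobile nucleosome generates downstream occupancy
        oscillations absent on barrier-free DNA (small-footprint analog)."""
        k = 21
        tr = uniform_potential(1200, -7.0, tss_offset=200)
        p = KineticParams(k_on=1.0, k_slide=0.0, active_shift=5.2, footprint_k=k)
        kev = np.exp(-7 + 5.2)
        t_end = 25 / kev
        bar = BarrierSpec(kind="fixed_nucleosome", fixed_start_j=-k)
        with_bar = run_ensemble(
            tr, p, bar, t_end=t_end, snapshot_times=[t_end],
            n_replicas=600, base_seed=17, record_events=False,
        )
        without = run_ensemble(
            tr, p, None, t_end=t_end, snapshot_times=[t_end],
            n_replicas=600, base_seed=18, record_events=False,
        )
        win = (5, 200)
        amp_bar = oscillation_amplitude(occupancy_profile(with_bar, t_end), win)
        amp_flat = oscillation_amplitude(occupancy_profile(without, t_end), win)
        assert amp_bar > 2.0 * amp_flat

    def test_fixed_nucleosome_always_present(self):
        tr = uniform_potential(300, -2.0)
        bar = BarrierSpec(kind="fixed_nucleosome", fixed_start_j=100)
        log = run_trajectory(
            tr, KineticParams(k_on=1.0, k_slide=0.5, footprint_k=6), bar,
            t_end=30.0, seed=3,
        )
        for t in np.linspace(0, 30, 20):
            assert 100 in replay_state(log, t)
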