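import numpy as np
import pytest

from nucdyn import (
    KineticParams,
    OccupancyProfile,
    barrier_deviation,
    exposure_deviation,
    exposure_statistics,
    fit_exponential_decay,
    mean_density,
    occupancy_profile,
    oscillation_amplitude,
    relaxation_curve,
    run_ensemble,
    sensitivity_scan,
)
from nucdyn.simulate import EnsembleResult, EventLog
from nucdyn.tracks import uniform_potential


def make_log(
    events,
    length_bp=40,
    k=10,
    t_end=30.0,
    initial=(),
    tss_offset=0,
):
    """Hand-constructed event log: events = [(t, kind, pos_before, pos_after)]."""
    times = np.array([e[0] for e in events], dtype=float)
    kind_code = {"adsorb": 0, "desorb": 1, "slide": 2}
    return EventLog(
        replica_id=0,
        seed=0,
        length_bp=length_bp,
        footprint_k=k,
        t_start=0.0,
        t_end=t_end,
        times=times,
        kinds=np.array([kind_code[e[1]] for e in events], dtype=np.int8),
        pos_before=np.array([e[2] for e in events], dtype=np.int64),
        pos_after=np.array([e[3] for e in events], dtype=np.int64),
        snapshot_times=np.array([]),
        snapshots=[],
        initial_starts=np.array(initial, dtype=np.int64),
        final_starts=np.array([], dtype=np.int64),
        tss_offset=tss_offset,
    )


class TestExposureBookkeeping:
    def test_hand_case_two_exposures(self):
        # site [0,10) uncovered during [0,5) and [10,12) inside window [0,20]
        log = make_log(
            [
                (5.0, "adsorb", -1, 0),
                (10.0, "desorb", 0, -1),
                (12.0, "adsorb", -1, 0),
            ]
        )
        stats = exposure_statistics(log, site_length=10, window=(0.0, 20.0), n_sites=1)
        assert stats.n_e[0] == pytest.approx(2.0)
        assert stats.t_e[0] == pytest.approx(3.5)

    def test_permanently_covered_site_flagged_zero(self):
        log = make_log([], initial=[0])
        stats = exposure_statistics(log, site_length=10, window=(0.0, 20.0), n_sites=1)
        assert stats.n_e[0] == 0.0
        assert stats.t_e[0] == 0.0
        assert stats.never_exposed[0]

    def test_exposure_ongoing_at_window_start_counts_from_t1(self):
        # uncovered on [0, 8): window [5, 20] sees one event of length 3
        log = make_log([(8.0, "adsorb", -1, 0)])
        stats = exposure_statistics(log, site_length=10, window=(5.0, 20.0), n_sites=1)
        assert stats.n_e[0] == 1.0
        assert stats.t_e[0] == pytest.approx(3.0)

    def test_exposure_ending_before_window_not_counted(self):
        log = make_log([(4.0, "adsorb", -1, 0)])
        stats = exposure_statistics(log, site_length=10, window=(5.0, 20.0), n_sites=1)
        assert stats.n_e[0] == 0.0

    def test_slide_opens_and_closes_sites(self):
        # two sites [0,10) and [10,20); rod slides from 0 to 10
        log = make_log([(6.0, "slide", 0, 10)], initial=[0])
        stats = exposure_statistics(log, site_length=10, window=(0.0, 20.0), n_sites=2)
        # site 0 opens when the rod leaves at t=6; site 1 was open until then
        assert stats.n_e.tolist() == [1.0, 1.0]
        assert stats.exposed_time[0].tolist() == [14.0, 6.0]

    def test_conservation_exposed_plus_covered_equals_window(self):
        """Independent interval bookkeeping: exposed + covered = window length."""
        tr = uniform_potential(120, -1.0)
        p = KineticParams(k_on=1.0, k_slide=0.5, active_shift=0.3, footprint_k=6)
        ens = run_ensemble(tr, p, t_end=40.0, n_replicas=6, base_seed=2)
        w1, w2 = 10.0, 35.0
        n_sites = 12
        stats = exposure_statistics(ens, site_length=10, window=(w1, w2), n_sites=n_sites)
        from nucdyn.lattice import coverage_from_starts
        from nucdyn.simulate import replay_state

        for r, log in enumerate(ens.logs):
            # reference: integrate coverage indicator over event intervals
            breaks = np.unique(
                np.concatenate(([w1, w2], log.times[(log.times > w1) & (log.times < w2)]))
            )
            covered = np.zeros(n_sites)
            for lo, hi in zip(breaks[:-1], breaks[1:]):
                starts = replay_state(log, (lo + hi) / 2)
                cov = coverage_from_starts(starts, 120, 6)
                for m in range(n_sites):
                    if cov[m * 10 : (m + 1) * 10].sum() > 0:
                        covered[m] += hi - lo
            assert np.allclose(stats.exposed_time[r] + covered, w2 - w1, atol=1e-9)

    def test_ne_te_product_bounded_by_window(self):
        tr = uniform_potential(120, -1.0)
        p = KineticParams(k_on=1.0, k_slide=0.5, active_shift=0.3, footprint_k=6)
        ens = run_ensemble(tr, p, t_end=40.0, n_replicas=4, base_seed=9)
        stats = exposure_statistics(ens, site_length=10, window=(10.0, 35.0))
        assert (stats.exposed_time <= 25.0 + 1e-9).all()

    def test_window_outside_horizon_rejected(self):
        log = make_log([], t_end=30.0)
        with pytest.raises(ValueError):
            exposure_statistics(log, window=(0.0, 50.0))


class TestOccupancy:
    def test_static_single_nucleosome_indicator(self):
        logs = [make_log([], initial=[5], t_end=10.0) for _ in range(4)]
        ens = EnsembleResult(logs=logs, seeds=np.arange(4))
        prof = occupancy_profile(ens, 7.0)
        expect = np.zeros(40)
        expect[5:15] = 1.0
        assert np.array_equal(prof.p, expect)

    def test_empty_trajectories_zero(self):
        logs = [make_log([], t_end=10.0)]
        prof = occupancy_profile(EnsembleResult(logs=logs, seeds=np.array([0])), 1.0)
        assert np.all(prof.p == 0.0)

    def test_mean_density_profile_vs_state_agree(self):
        logs = [make_log([], initial=[0], t_end=5.0), make_log([], t_end=5.0)]
        prof = occupancy_profile(EnsembleResult(logs=logs, seeds=np.arange(2)), 1.0)
        assert mean_density(prof) == pytest.approx(0.5 * 10 / 40)

    def test_full_tiling_density(self):
        assert mean_density(np.ones(100)) == 1.0


class TestAmplitudeAndFits:
    def test_flat_profile_zero_amplitude(self):
        assert oscillation_amplitude(np.full(2000, 0.8), (200, 1500)) == 0.0

    def test_cosine_rms(self):
        j = np.arange(2000)
        p = 0.8 + 0.1 * np.cos(2 * np.pi * j / 165.0)
        amp = oscillation_amplitude(p, (200, 1500))
        assert amp == pytest.approx(0.1 / np.sqrt(2), rel=0.02)

    def test_length_fit_recovery(self):
        rng = np.random.default_rng(5)
        j = np.arange(3000, dtype=float)
        y = 0.3 * np.exp(-j / 800.0) + rng.normal(0, 0.01, size=3000)
        curve = barrier_deviation(np.clip(y, 0, None) + 0.5, np.full(3000, 0.5),
                                  tss_offset=0, noise_floor=0.01)
        assert curve.decay_const == pytest.approx(800.0, rel=0.05)

    def test_time_fit_recovery(self):
        t = np.linspace(0, 1500, 60)
        d = 0.2 * np.exp(-t / 300.0)
        profiles = [np.full(100, 0.5 + x) for x in d]
        curve = relaxation_curve(t, profiles, np.full(100, 0.5), noise_floor=1e-4)
        assert curve.decay_const == pytest.approx(300.0, rel=0.05)

    def test_identical_profiles_fit_rejected(self):
        p = np.full(2000, 0.7)
        curve = barrier_deviation(p, p, tss_offset=0, noise_floor=0.01)
        assert np.all(curve.y == 0.0)
        assert curve.decay_const is None

    def test_fit_window_reported_within_data(self):
        x = np.arange(200, dtype=float)
        y = np.exp(-x / 40.0)
        decay, amp, window, r2 = fit_exponential_decay(x, y, noise_floor=0.01)
        assert decay == pytest.approx(40.0, rel=1e-6)
        assert window[0] >= 0 and window[1] <= 199
        assert r2 > 0.999


class TestExposureDeviation:
    def _stats(self, te):
        from nucdyn.analysis import ExposureStats

        n = len(te)
        return ExposureStats(
            site_start_j=np.arange(n) * 10,
            site_length=10,
            window=(0.0, 100.0),
            counts=np.ones((1, n), dtype=np.int64),
            exposed_time=np.asarray(te, dtype=float)[None, :],
        )

    def test_identical_zero(self):
        s = self._stats(np.linspace(1, 2, 30))
        curve = exposure_deviation(s, s)
        assert np.all(curve.y == 0.0)

    def test_exponential_recovery(self):
        rng = np.random.default_rng(8)
        x = np.arange(120) * 10.0
        base = np.full(120, 5.0)
        dev = 4.0 * np.exp(-x / 400.0) + rng.normal(0, 0.04, 120)
        curve = exposure_deviation(
            self._stats(base + dev), self._stats(base), noise_floor=0.04
        )
        assert curve.decay_const == pytest.approx(400.0, rel=0.05)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            exposure_deviation(self._stats([1.0, 2.0]), self._stats([1.0]))


class TestSensitivity:
    def test_zero_shift_zero_changes(self):
        tr = uniform_potential(400, -2.0)
        p = KineticParams(k_on=1.0, k_slide=0.3, active_shift=0.5, footprint_k=6)
        res = sensitivity_scan(
            tr, p, dv=0.0, t_end=30.0, window=(10.0, 30.0),
            n_replicas=4, base_seed=1, n_boot=10,
        )
        assert res.density_rel_change == 0.0
        assert res.ne_rel_change == 0.0

    def test_k1_toy_matches_independent_site_formula(self):
        """k=1 lattice: equilibrium density is z/(1+z); a dV shift changes it
        by a closed-form amount the paired simulation must reproduce."""
        v, dv, va = -1.0, 1.0, 0.5
        tr = uniform_potential(300, v)
        p = KineticParams(k_on=1.0, k_slide=0.0, active_shift=va, footprint_k=1)
        z0 = np.exp(-(v + va))
        z1 = np.exp(-(v + dv + va))
        expected = abs(z0 / (1 + z0) - z1 / (1 + z1)) / (z0 / (1 + z0))
        res = sensitivity_scan(
            tr, p, dv=dv, t_end=60.0, window=(30.0, 60.0),
            n_replicas=60, base_seed=3, n_boot=40,
        )
        assert res.density_rel_change == pytest.approx(expected, abs=0.03)
        assert res.density_ci[0] - 0.03 < expected < res.density_ci[1] + 0.03


class TestAntiCorrelationInvariant:
    def test_occupancy_exposure_anticorrelation_near_barrier(self):
        """Occupancy peaks imply short exposure times (small-footprint analog)."""
        from nucdyn import BarrierSpec

        k = 21
        tr = uniform_potential(800, -7.0, tss_offset=200)
        p = KineticParams(k_on=1.0, k_slide=0.2, active_shift=5.2, footprint_k=k)
        bar = BarrierSpec(kind="hard", start_j=-30, end_j=-1)
        ens = run_ensemble(
            tr, p, bar, t_end=400.0, snapshot_times=[400.0],
            n_replicas=150, base_seed=6,
        )
        prof = occupancy_profile(ens, 400.0)
        stats = exposure_statistics(ens, site_length=10, window=(200.0, 400.0), n_sites=30)
        occ = prof.p[200:500].reshape(30, 10).mean(axis=1)
        r = np.corrcoef(occ, stats.t_e)[0, 1]
        assert r < -0.3
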