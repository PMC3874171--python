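"""Trajectory and ensemble drivers for the stochastic nucleosome model.

``run_trajectory`` simulates one replica from naked DNA (or a supplied
initial state) with the compiled kernel and returns an :class:`EventLog`;
``run_ensemble`` runs independent replicas with reproducibly derived seeds.
``gillespie_step`` is a plain-Python single-step reference implementation of
the same dynamics, kept deliberately separate from the kernel so the two can
be cross-checked.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .barriers import BarrierSpec
from .equilibrium import percus_occupancy
from .lattice import (
    KineticParams,
    LatticeState,
    coverage_from_starts,
    eligible_adsorption_starts,
)
from .tracks import PotentialTrack

__all__ = [
    "EventLog",
    "EnsembleResult",
    "gillespie_step",
    "run_trajectory",
    "run_ensemble",
    "replay_state",
    "calibrate_activity",
    "derive_seeds",
]

EVENT_NAMES = {0: "adsorb", 1: "desorb", 2: "slide"}


@dataclass
class EventLog:
    """Time-ordered event record of one replica plus state snapshots."""

    replica_id: int
    seed: int
    length_bp: int
    footprint_k: int
    t_start: float
    t_end: float
    times: np.ndarray
    kinds: np.ndarray
    pos_before: np.ndarray
    pos_after: np.ndarray
    snapshot_times: np.ndarray
    snapshots: list[np.ndarray]
    initial_starts: np.ndarray
    final_starts: np.ndarray
    events_recorded: bool = True
    tss_offset: int = 0
    fixed_start: int | None = None

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def snapshot_at(self, t: float) -> np.ndarray | None:
        hits = np.flatnonzero(np.isclose(self.snapshot_times, t, rtol=0, atol=1e-9))
        if hits.size:
            return self.snapshots[int(hits[0])]
        return None

    def state_at(self, t: float) -> np.ndarray:
        """Nucleosome starts at time ``t`` (snapshot lookup, else replay)."""
        snap = self.snapshot_at(t)
        if snap is not None:
            return snap
        if not self.events_recorded:
            raise ValueError(
                f"no snapshot at t={t} and events were not recorded"
            )
        return replay_state(self, t)


@dataclass
class EnsembleResult:
    """Replica event logs plus the configuration fingerprint."""

    logs: list[EventLog]
    seeds: np.ndarray
    config_hash: str = ""

    @property
    def n_replicas(self) -> int:
        return len(self.logs)

    @property
    def length_bp(self) -> int:
        return self.logs[0].length_bp

    @property
    def footprint_k(self) -> int:
        return self.logs[0].footprint_k


def replay_state(log: EventLog, t: float) -> np.ndarray:
    """Reconstruct the sorted start positions at time ``t`` from the log."""
    if t < log.t_start or t > log.t_end:
        raise ValueError(f"t={t} outside simulated horizon [{log.t_start}, {log.t_end}]")
    starts = set(int(s) for s in log.initial_starts)
    upto = int(np.searchsorted(log.times, t, side="right"))
    for m in range(upto):
        kind = log.kinds[m]
        if kind == _kernel.EV_ADSORB:
            starts.add(int(log.pos_after[m]))
        elif kind == _kernel.EV_DESORB:
            starts.remove(int(log.pos_before[m]))
        else:
            starts.remove(int(log.pos_before[m]))
            starts.add(int(log.pos_after[m]))
    return np.array(sorted(starts), dtype=np.int64)


def _engine_inputs(
    track: PotentialTrack, params: KineticParams, barrier: BarrierSpec
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-start off rates, allowed prefix sums, and hard-barrier interval."""
    N = track.length_bp
    k = params.footprint_k
    n_pos = N - k + 1
    if n_pos <= 0:
        raise ValueError("footprint larger than lattice")
    v = track.values[:n_pos]
    allowed = np.isfinite(v)
    bar_lo = bar_hi = -1
    if barrier.kind == "hard":
        bar_lo, bar_hi = barrier.absolute_interval(track.tss_offset)
        if bar_lo < 0 or bar_hi >= N:
            raise ValueError("hard barrier outside lattice")
        lo = max(0, bar_lo - k + 1)
        allowed = allowed.copy()
        allowed[lo : min(bar_hi + 1, n_pos)] = False
    # off rates are defined wherever the track energy is finite — including
    # starts overlapping a freshly inserted hard barrier (such nucleosomes are
    # immobilized but still decay by eviction); only track-forbidden starts
    # (never occupied) carry rate 0
    finite = np.isfinite(v)
    roff = np.zeros(n_pos, dtype=np.float64)
    roff[finite] = params.off_scale * np.exp(v[finite] + params.active_shift)
    apre = np.zeros(n_pos + 1, dtype=np.int64)
    np.cumsum(allowed, out=apre[1:])
    return roff, apre, bar_lo, bar_hi


def run_trajectory(
    track: PotentialTrack,
    params: KineticParams,
    barrier: BarrierSpec | None = None,
    t_end: float = 3600.0,
    snapshot_times: np.ndarray | list[float] | None = None,
    seed: int = 0,
    initial_starts: np.ndarray | None = None,
    t_start: float = 0.0,
    record_events: bool = True,
    replica_id: int = 0,
) -> EventLog:
    """Simulate one replica from ``t_start`` to ``t_end``.

    Starts from naked DNA unless ``initial_starts`` is given.  A
    ``fixed_nucleosome`` barrier installs its immobile nucleosome before the
    run.  Deterministic given ``(inputs, seed)``.
    """
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    barrier = barrier or BarrierSpec()
    N, k = track.length_bp, params.footprint_k
    roff, apre, bar_lo, bar_hi = _engine_inputs(track, params, barrier)

    cap = N // k + 2
    starts = np.zeros(cap, dtype=np.int64)
    fixed_start = -1
    init = np.empty(0, dtype=np.int64)
    if initial_starts is not None:
        init = np.sort(np.asarray(initial_starts, dtype=np.int64))
    if barrier.kind == "fixed_nucleosome":
        fixed_start = barrier.fixed_start_j + track.tss_offset
        if fixed_start < 0 or fixed_start > N - k:
            raise ValueError("fixed nucleosome outside lattice")
        if fixed_start not in init:
            init = np.sort(np.append(init, fixed_start))
    n0 = init.size
    if n0 > cap:
        raise ValueError("too many initial nucleosomes")

    snap_times = (
        np.array([], dtype=np.float64)
        if snapshot_times is None
        else np.asarray(snapshot_times, dtype=np.float64)
    )
    if snap_times.size and (np.diff(snap_times) < 0).any():
        raise ValueError("snapshot_times must be sorted")
    snap_out = np.full((snap_times.size, cap), -1, dtype=np.int64)
    snap_n = np.zeros(snap_times.size, dtype=np.int64)

    # generous first guess for the event capacity; retried on overflow
    horizon = t_end - t_start
    mean_occ = max(cap, 8)
    max_off = float(roff.max()) if roff.size else 0.0
    guess = (
        params.k_on * (N - k + 1) * min(horizon, 10.0 / max(params.k_on, 1e-12))
        + mean_occ * (params.k_slide + min(max_off, 10.0)) * horizon
    )
    ev_cap = int(min(max(4 * guess + 1000, 10000), 5e7)) if record_events else 0

    while True:
        starts[:n0] = init
        ev_t = np.empty(ev_cap, dtype=np.float64)
        ev_kind = np.empty(ev_cap, dtype=np.int8)
        ev_pb = np.empty(ev_cap, dtype=np.int64)
        ev_pa = np.empty(ev_cap, dtype=np.int64)
        status, n_ev, n_fin, t_fin = _kernel.run_kmc(
            N,
            k,
            roff,
            apre,
            params.k_on,
            params.k_slide,
            bar_lo,
            bar_hi,
            fixed_start,
            starts,
            n0,
            t_start,
            t_end,
            snap_times,
            snap_out,
            snap_n,
            ev_t,
            ev_kind,
            ev_pb,
            ev_pa,
            record_events,
            int(seed) & 0x7FFFFFFF,
        )
        if status == _kernel.STATUS_OK:
            break
        ev_cap = max(2 * ev_cap, 100000)  # rerun deterministically, larger buffer

    snapshots = [snap_out[i, : snap_n[i]].copy() for i in range(snap_times.size)]
    return EventLog(
        replica_id=replica_id,
        seed=int(seed),
        length_bp=N,
        footprint_k=k,
        t_start=t_start,
        t_end=t_end,
        times=ev_t[:n_ev].copy(),
        kinds=ev_kind[:n_ev].copy(),
        pos_before=ev_pb[:n_ev].copy(),
        pos_after=ev_pa[:n_ev].copy(),
        snapshot_times=snap_times.copy(),
        snapshots=snapshots,
        initial_starts=init.copy(),
        final_starts=starts[:n_fin].copy(),
        events_recorded=bool(record_events),
        tss_offset=track.tss_offset,
        fixed_start=None if fixed_start < 0 else fixed_start,
    )


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Reproducible, pairwise-distinct 31-bit replica seeds."""
    ss = np.random.SeedSequence(base_seed)
    out: list[int] = []
    seen: set[int] = set()
    processed = 0
    draw = max(2 * n, 64)
    while len(out) < n:
        pool = ss.generate_state(draw, dtype=np.uint64) & 0x7FFFFFFF
        for s in pool[processed:]:
            processed += 1
            s = int(s)
            if s not in seen:  # drop 31-bit birthday collisions deterministically
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
        draw *= 2
    seeds = np.array(out, dtype=np.int64)
    if np.unique(seeds).size != n:
        raise RuntimeError("duplicate derived seeds")
    return seeds


def run_ensemble(
    track: PotentialTrack,
    params: KineticParams,
    barrier: BarrierSpec | None = None,
    t_end: float = 3600.0,
    snapshot_times=None,
    n_replicas: int = 100,
    base_seed: int = 0,
    record_events: bool = True,
    initial_starts_per_replica: list[np.ndarray] | None = None,
    t_start: float = 0.0,
    config_hash: str = "",
) -> EnsembleResult:
    """Independent replicas with seeds derived from ``base_seed``.

    The result depends only on the inputs and ``base_seed``, regardless of
    execution order.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    seeds = derive_seeds(base_seed, n_replicas)
    logs = []
    for r in range(n_replicas):
        init = (
            initial_starts_per_replica[r]
            if initial_starts_per_replica is not None
            else None
        )
        logs.append(
            run_trajectory(
                track,
                params,
                barrier,
                t_end=t_end,
                snapshot_times=snapshot_times,
                seed=int(seeds[r]),
                initial_starts=init,
                t_start=t_start,
                record_events=record_events,
                replica_id=r,
            )
        )
    return EnsembleResult(logs=logs, seeds=seeds, config_hash=config_hash)


def gillespie_step(
    state: LatticeState,
    track: PotentialTrack,
    params: KineticParams,
    rng: np.random.Generator,
):
    """One exact stochastic step (reference implementation).

    Returns ``(new_state, dt, event)`` with ``event = (kind, pos_before,
    pos_after)``.  Raises ``RuntimeError`` when the total rate is zero
    (absorbing state).
    """
    eligible = eligible_adsorption_starts(state, track)
    a_ads = params.k_on * eligible.size
    mobile = [
        m for m in range(state.n_nucleosomes) if state.starts[m] != (state.fixed_start if state.fixed_start is not None else -1)
    ]
    roffs = np.array(
        [
            params.off_scale
            * math.exp(track.values[state.starts[m]] + params.active_shift)
            for m in mobile
        ]
    )
    a_off = float(roffs.sum())
    a_slide = params.k_slide * len(mobile)
    R = a_ads + a_off + a_slide
    if R <= 0:
        raise RuntimeError("absorbing state: all rates are zero")
    dt = rng.exponential(1.0 / R)
    x = rng.random() * R
    new = state.copy()
    if x < a_ads:
        pos = int(eligible[min(int(x / params.k_on), eligible.size - 1)])
        new.starts = np.sort(np.append(new.starts, pos))
        event = ("adsorb", -1, pos)
    elif x < a_ads + a_off:
        y = x - a_ads
        idx = mobile[int(np.searchsorted(np.cumsum(roffs), y, side="right"))]
        pos = int(new.starts[idx])
        new.starts = np.delete(new.starts, idx)
        event = ("desorb", pos, -1)
    else:
        from .lattice import execute_slide

        m_idx = mobile[min(int((x - a_ads - a_off) / params.k_slide), len(mobile) - 1)]
        direction = "right" if rng.random() < 0.5 else "left"
        pb = int(new.starts[m_idx])
        new = execute_slide(new, m_idx, direction)
        pa = int(new.starts[m_idx])
        new.starts = np.sort(new.starts)
        event = ("slide", pb, pa)
    new.validate()
    return new, float(dt), event


def steady_state_density(
    track: PotentialTrack,
    params: KineticParams,
    barrier: BarrierSpec | None = None,
    n_replicas: int = 24,
    base_seed: int = 0,
) -> float:
    """Mean coverage in steady state, measured over the last third of a run.

    The horizon is set adaptively to ~20 mean eviction times so the estimate
    is insensitive to the initial naked-DNA condition.
    """
    k_evict = params.off_scale * math.exp(track.mean_level + params.active_shift)
    t_end = max(20.0 / max(k_evict, 1e-9), 30.0 / max(params.k_on, 1e-9))
    snap = np.linspace(2 * t_end / 3, t_end, 6)
    ens = run_ensemble(
        track,
        params,
        barrier,
        t_end=t_end,
        snapshot_times=snap,
        n_replicas=n_replicas,
        base_seed=base_seed,
        record_events=False,
    )
    k = params.footprint_k
    total = 0.0
    count = 0
    for log in ens.logs:
        for s in log.snapshots:
            total += coverage_from_starts(s, track.length_bp, k).mean()
            count += 1
    return total / count


def calibrate_activity(
    track: PotentialTrack,
    params: KineticParams,
    target_density: float = 0.85,
    tolerance: float = 0.01,
    barrier: BarrierSpec | None = None,
    bracket: tuple[float, float] = (0.0, 14.0),
    base_seed: int = 0,
    n_replicas: int = 24,
    method: str = "auto",
) -> float:
    """Find the eviction shift V_a giving a target steady-state coverage.

    Exploits that coverage decreases monotonically in V_a and bisects the
    bracket.  With ``k_slide = 0`` the steady state is the exact hard-rod
    equilibrium at potential ``V + V_a``, so the Percus oracle is used;
    otherwise short simulated ensembles estimate the density.
    """
    k = params.footprint_k
    if not 0.0 < target_density < 1.0:
        raise ValueError("target_density must be in (0, 1)")
    use_percus = method == "percus" or (method == "auto" and params.k_slide == 0.0)

    def density(va: float) -> float:
        if use_percus:
            return float(percus_occupancy(track, k, active_shift=va).mean())
        return steady_state_density(
            track,
            params.with_shift(va),
            barrier,
            n_replicas=n_replicas,
            base_seed=base_seed,
        )

    # density decreases monotonically in V_a; bisect without evaluating the
    # expensive low-V_a endpoint (its near-thermal horizon is enormous)
    lo, hi = bracket
    d_hi = density(hi)
    if d_hi > target_density:
        raise ValueError(
            f"target density {target_density} unreachable: coverage is still "
            f"{d_hi:.4f} at V_a = {hi}"
        )
    best = hi
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        d_mid = density(mid)
        best = mid
        if abs(d_mid - target_density) <= tolerance and hi - lo < 0.5:
            return mid
        if d_mid > target_density:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    d_best = density(best)
    if abs(d_best - target_density) > 4 * tolerance:
        raise ValueError(
            f"calibration failed: coverage {d_best:.4f} at V_a = {best:.3f} "
            f"vs target {target_density} (bracket [{bracket[0]}, {bracket[1]}])"
        )
    return best


def config_fingerprint(payload: str) -> str:
    """Short content hash used to stamp output files."""
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
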