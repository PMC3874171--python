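"""Exact equilibrium and finite-time oracles for hard rods on a lattice.

The thermal reference of the model is the grand-canonical Tonks gas: hard
rods of length ``k`` on an ``N``-bp lattice with position-dependent activity
``z_i = exp(-(V_i + V_a))``.  ``percus_occupancy`` evaluates its exact
per-bp coverage by forward/backward partition-function recursions in O(N),
the lattice analog of the classic continuum treatment of an inhomogeneous
hard-rod fluid.  ``enumerate_equilibrium`` brute-forces the same average by
summing over every configuration, and ``master_equation_occupancy``
integrates the full continuous-time Markov chain on small lattices — both
exist purely as independent correctness oracles for the simulator.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

from .barriers import BarrierSpec
from .lattice import KineticParams, coverage_from_starts
from .tracks import PotentialTrack

__all__ = [
    "percus_occupancy",
    "enumerate_equilibrium",
    "master_equation_occupancy",
    "count_configurations",
]


def _log_activities(track: PotentialTrack, k: int, active_shift: float) -> np.ndarray:
    n_pos = track.length_bp - k + 1
    if n_pos <= 0:
        raise ValueError("footprint larger than lattice")
    v = track.values[:n_pos]
    logz = np.where(np.isfinite(v), -(v + active_shift), -np.inf)
    return logz


def percus_occupancy(
    track: PotentialTrack, k: int = 147, active_shift: float = 0.0
) -> np.ndarray:
    """Exact equilibrium per-bp coverage of hard rods in a potential.

    Log-domain recursions keep the computation stable for arbitrarily long
    lattices and deep potentials.  Forbidden starts carry activity zero, so
    coverage inside a hard barrier is identically 0.

    Returns an array of length ``track.length_bp`` with values in [0, 1].
    """
    N = track.length_bp
    logz = _log_activities(track, k, active_shift)
    n_pos = logz.size

    # lf[m] = log partition function of the first m base pairs
    lf = np.zeros(N + 1)
    for m in range(k, N + 1):
        lf[m] = np.logaddexp(lf[m - 1], logz[m - k] + lf[m - k])
    # lb[m] = log partition function of base pairs [m, N)
    lb = np.zeros(N + 1)
    for m in range(N - k, -1, -1):
        lb[m] = np.logaddexp(lb[m + 1], logz[m] + lb[m + k])

    with np.errstate(invalid="ignore"):
        logp = logz + lf[:n_pos] + lb[k:] - lf[N]
    p_start = np.exp(logp)
    p_start[~np.isfinite(logp)] = 0.0

    cum = np.concatenate(([0.0], np.cumsum(p_start)))
    cov = np.empty(N)
    for m in range(N):
        lo = max(0, m - k + 1)
        hi = min(m, n_pos - 1)
        cov[m] = cum[hi + 1] - cum[lo] if hi >= lo else 0.0
    return np.clip(cov, 0.0, 1.0)


def count_configurations(length_bp: int, k: int) -> int:
    """Number of distinct hard-rod configurations on the lattice."""
    a = [1] * min(k, length_bp + 1)
    for m in range(k, length_bp + 1):
        a.append(a[m - 1] + a[m - k])
    return a[length_bp]


MAX_ENUM_CONFIGS = 10_000_000


def _enumerate_states(
    length_bp: int, k: int, allowed: np.ndarray
) -> list[tuple[int, ...]]:
    """All hard-rod configurations (tuples of sorted starts)."""
    states: list[tuple[int, ...]] = []
    n_pos = length_bp - k + 1

    def rec(pos: int, cur: list[int]) -> None:
        states.append(tuple(cur))
        for p in range(pos, n_pos):
            if allowed[p]:
                cur.append(p)
                rec(p + k, cur)
                cur.pop()

    rec(0, [])
    return states


def enumerate_equilibrium(
    track: PotentialTrack, k: int = 147, active_shift: float = 0.0
) -> np.ndarray:
    """Brute-force Boltzmann-average coverage (small lattices only).

    Each configuration is weighted by the product of ``exp(-(V_i + V_a))``
    over its rod starts.  Guarded by the total configuration count; larger
    systems must use :func:`percus_occupancy`.
    """
    N = track.length_bp
    if count_configurations(N, k) > MAX_ENUM_CONFIGS:
        raise ValueError(
            "too many configurations to enumerate; use percus_occupancy"
        )
    logz = _log_activities(track, k, active_shift)
    allowed = np.isfinite(logz)
    total_w = 0.0
    cov = np.zeros(N)
    for cfg in _enumerate_states(N, k, allowed):
        w = float(np.exp(sum(logz[list(cfg)]))) if cfg else 1.0
        total_w += w
        for s in cfg:
            cov[s : s + k] += w
    return cov / total_w


def master_equation_occupancy(
    track: PotentialTrack,
    params: KineticParams,
    t: float,
    barrier: BarrierSpec | None = None,
    initial_starts: tuple[int, ...] = (),
) -> np.ndarray:
    """Exact expected coverage at time ``t`` of the full Markov chain.

    Enumerates every hard-rod configuration, builds the continuous-time
    generator for adsorption/desorption/slide-to-contact moves, and
    integrates the forward equation from the given initial configuration
    (default: naked DNA).  Small lattices only (same guard as enumeration).
    """
    barrier = barrier or BarrierSpec()
    N, k = track.length_bp, params.footprint_k
    if count_configurations(N, k) > 20_000:
        raise ValueError("configuration space too large for the master equation")

    n_pos = N - k + 1
    allowed = np.isfinite(track.values[:n_pos])
    bar_lo = bar_hi = None
    if barrier.kind == "hard":
        bar_lo, bar_hi = barrier.absolute_interval(track.tss_offset)
        for p in range(max(0, bar_lo - k + 1), min(bar_hi + 1, n_pos)):
            allowed[p] = False
    fixed_start = None
    if barrier.kind == "fixed_nucleosome":
        fixed_start = barrier.fixed_start_j + track.tss_offset
        initial_starts = tuple(sorted(set(initial_starts) | {fixed_start}))

    states = _enumerate_states(N, k, allowed)
    if fixed_start is not None:
        states = [s for s in states if fixed_start in s]
    index = {s: m for m, s in enumerate(states)}
    n_states = len(states)

    roff = params.off_scale * np.exp(
        np.where(allowed, track.values[:n_pos], 0.0) + params.active_shift
    )

    def slide_target(cfg: tuple[int, ...], i: int, right: bool) -> int:
        cur = cfg[i]
        if right:
            limit = N
            if i + 1 < len(cfg):
                limit = cfg[i + 1]
            if bar_lo is not None and bar_lo >= cur + k and bar_lo < limit:
                limit = bar_lo
            return limit - k
        limit = 0
        if i > 0:
            limit = cfg[i - 1] + k
        if bar_hi is not None and bar_hi < cur and bar_hi + 1 > limit:
            limit = bar_hi + 1
        return limit

    rows, cols, vals = [], [], []

    def add(src: int, dst: int, rate: float) -> None:
        rows.append(src)
        cols.append(dst)
        vals.append(rate)

    for m, cfg in enumerate(states):
        occupied = np.zeros(N, dtype=bool)
        for s in cfg:
            occupied[s : s + k] = True
        if bar_lo is not None:
            occupied[bar_lo : bar_hi + 1] = True
        for p in range(n_pos):
            if allowed[p] and not occupied[p : p + k].any():
                dst = index[tuple(sorted(cfg + (p,)))]
                add(m, dst, params.k_on)
        for i, s in enumerate(cfg):
            if s == fixed_start:
                continue
            dst = index[tuple(x for x in cfg if x != s)]
            add(m, dst, float(roff[s]))
            if params.k_slide > 0:
                for right in (False, True):
                    tgt = slide_target(cfg, i, right)
                    if tgt != s:
                        new = list(cfg)
                        new[i] = tgt
                        add(m, index[tuple(sorted(new))], params.k_slide / 2.0)

    gen = scipy.sparse.coo_matrix(
        (vals, (rows, cols)), shape=(n_states, n_states)
    ).tocsr()
    diag = np.asarray(gen.sum(axis=1)).ravel()
    gen = gen - scipy.sparse.diags(diag)

    p0 = np.zeros(n_states)
    p0[index[tuple(sorted(initial_starts))]] = 1.0
    if n_states <= 1500:
        pt = p0 @ scipy.linalg.expm(gen.toarray() * t)
    else:
        pt = scipy.sparse.linalg.expm_multiply(gen.T * t, p0)

    cov = np.zeros(N)
    for m, cfg in enumerate(states):
        if pt[m] != 0.0 and cfg:
            cov += pt[m] * coverage_from_starts(np.array(cfg), N, k)
    return cov
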