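"""Compiled continuous-time Monte Carlo core.

This module is the production fast path of the simulator: a single numba
``njit`` loop implementing exactly the moves defined in :mod:`nucdyn.lattice`
(adsorption per eligible start, Boltzmann/active removal per nucleosome,
slide-to-contact per nucleosome).  Correctness is anchored by the test
suite, which compares trajectories of this kernel against the exact
master-equation and Percus oracles.

State layout passed to the kernel:

* ``starts`` — int64 array of capacity ``N // k + 2``; the first ``n``
  entries are the sorted nucleosome start positions (mutated in place);
* ``roff`` — off-rate per start position (0 at forbidden starts);
* ``apre`` — prefix sums of the allowed-start mask, ``apre[m]`` = number of
  allowed start positions ``< m`` (used both to count eligible starts per
  gap in O(1) and to sample a uniform allowed position by binary search);
* ``bar_lo, bar_hi`` — closed absolute interval of a hard barrier (-1,-1 if
  none); ``fixed_start`` — absolute start of an immobile nucleosome (-1 if
  none).

Event codes: 0 = adsorb, 1 = desorb, 2 = slide.  A blocked slide is recorded
with ``pos_after == pos_before``.  Snapshots are taken at the requested
(sorted) times; the state at time ``s`` is the state after all events with
``t <= s``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_EVENT_OVERFLOW = 1

EV_ADSORB = 0
EV_DESORB = 1
EV_SLIDE = 2


@njit(cache=True)
def _count_eligible(starts, n, bar_lo, bar_hi, N, k, apre):
    """Number of allowed, empty start positions, walking free gaps."""
    total = 0
    prev = 0
    i = 0
    bar_pending = bar_lo >= 0
    while i < n or bar_pending:
        if bar_pending and (i >= n or bar_lo < starts[i]):
            o_lo = bar_lo
            o_end = bar_hi + 1
            bar_pending = False
        else:
            o_lo = starts[i]
            o_end = starts[i] + k
            i += 1
        if o_lo - k >= prev:
            total += apre[o_lo - k + 1] - apre[prev]
        if o_end > prev:
            prev = o_end
    if N - k >= prev:
        total += apre[N - k + 1] - apre[prev]
    return total


@njit(cache=True)
def _pick_eligible(starts, n, bar_lo, bar_hi, N, k, apre, target):
    """Return the (target+1)-th allowed empty start (0-based target)."""
    remaining = target
    prev = 0
    i = 0
    bar_pending = bar_lo >= 0
    while True:
        if i < n or bar_pending:
            if bar_pending and (i >= n or bar_lo < starts[i]):
                o_lo = bar_lo
                o_end = bar_hi + 1
                bar_pending = False
            else:
                o_lo = starts[i]
                o_end = starts[i] + k
                i += 1
            gap_hi = o_lo - k  # last eligible start in this gap
        else:
            o_end = -1
            gap_hi = N - k
        if gap_hi >= prev:
            cnt = apre[gap_hi + 1] - apre[prev]
            if remaining < cnt:
                # binary search for the position with cumulative count
                want = apre[prev] + remaining + 1
                lo, hi = prev, gap_hi + 1
                while lo < hi:
                    mid = (lo + hi) // 2
                    if apre[mid + 1] >= want:
                        hi = mid
                    else:
                        lo = mid + 1
                return lo
            remaining -= cnt
        if o_end < 0:
            return -1  # inconsistent count (should not happen)
        if o_end > prev:
            prev = o_end


@njit(cache=True)
def _slide_target(starts, n, idx, go_right, bar_lo, bar_hi, N, k):
    cur = starts[idx]
    if go_right:
        limit = N
        if idx + 1 < n:
            limit = starts[idx + 1]
        if bar_lo >= cur + k and bar_lo < limit:
            limit = bar_lo
        return limit - k
    else:
        limit = 0
        if idx > 0:
            limit = starts[idx - 1] + k
        if bar_hi >= 0 and bar_hi < cur and bar_hi + 1 > limit:
            limit = bar_hi + 1
        return limit


@njit(cache=True)
def run_kmc(
    N,
    k,
    roff,
    apre,
    k_on,
    k_slide,
    bar_lo,
    bar_hi,
    fixed_start,
    starts,
    n0,
    t0,
    t_end,
    snap_times,
    snap_out,
    snap_n,
    ev_t,
    ev_kind,
    ev_pb,
    ev_pa,
    record,
    seed,
):
    """Simulate from time ``t0`` to ``t_end``; returns (status, n_events, n, t)."""
    np.random.seed(seed)
    n = n0
    t = t0
    n_ev = 0
    si = 0
    n_snap = snap_times.size
    ev_cap = ev_t.size

    while True:
        # --- propensities -------------------------------------------------
        n_elig = _count_eligible(starts, n, bar_lo, bar_hi, N, k, apre)
        a_ads = k_on * n_elig
        a_off = 0.0
        for m in range(n):
            if starts[m] != fixed_start:
                a_off += roff[starts[m]]
        n_mobile = n
        if fixed_start >= 0:
            n_mobile -= 1
        a_slide = k_slide * n_mobile
        R = a_ads + a_off + a_slide

        if R <= 0.0:
            # absorbing state: nothing can happen until t_end
            while si < n_snap and snap_times[si] <= t_end:
                for m in range(n):
                    snap_out[si, m] = starts[m]
                snap_n[si] = n
                si += 1
            t = t_end
            return STATUS_OK, n_ev, n, t

        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        t_next = t + (-np.log(u) / R)

        # snapshots strictly before the next event
        while si < n_snap and snap_times[si] < t_next and snap_times[si] <= t_end:
            for m in range(n):
                snap_out[si, m] = starts[m]
            snap_n[si] = n
            si += 1

        if t_next > t_end:
            t = t_end
            return STATUS_OK, n_ev, n, t
        t = t_next

        # --- choose and execute the event ---------------------------------
        x = np.random.random() * R
        if x < a_ads:
            target = int(x / k_on)
            if target >= n_elig:
                target = n_elig - 1
            pos = _pick_eligible(starts, n, bar_lo, bar_hi, N, k, apre, target)
            # sorted insert
            ins = n
            for m in range(n):
                if starts[m] > pos:
                    ins = m
                    break
            for m in range(n, ins, -1):
                starts[m] = starts[m - 1]
            starts[ins] = pos
            n += 1
            if record:
                if n_ev >= ev_cap:
                    return STATUS_EVENT_OVERFLOW, n_ev, n, t
                ev_t[n_ev] = t
                ev_kind[n_ev] = EV_ADSORB
                ev_pb[n_ev] = -1
                ev_pa[n_ev] = pos
                n_ev += 1
        elif x < a_ads + a_off:
            y = x - a_ads
            acc = 0.0
            idx = -1
            for m in range(n):
                if starts[m] == fixed_start:
                    continue
                acc += roff[starts[m]]
                if y < acc:
                    idx = m
                    break
            if idx < 0:  # float round-off: take last mobile
                for m in range(n - 1, -1, -1):
                    if starts[m] != fixed_start:
                        idx = m
                        break
            pos = starts[idx]
            for m in range(idx, n - 1):
                starts[m] = starts[m + 1]
            n -= 1
            if record:
                if n_ev >= ev_cap:
                    return STATUS_EVENT_OVERFLOW, n_ev, n, t
                ev_t[n_ev] = t
                ev_kind[n_ev] = EV_DESORB
                ev_pb[n_ev] = pos
                ev_pa[n_ev] = -1
                n_ev += 1
        else:
            m_target = int((x - a_ads - a_off) / k_slide)
            if m_target >= n_mobile:
                m_target = n_mobile - 1
            idx = -1
            cnt = 0
            for m in range(n):
                if starts[m] == fixed_start:
                    continue
                if cnt == m_target:
                    idx = m
                    break
                cnt += 1
            go_right = np.random.random() < 0.5
            pb = starts[idx]
            if bar_lo >= 0 and pb <= bar_hi and pb + k > bar_lo:
                pa = pb  # nucleosome caught under an inserted barrier: immobile
            else:
                pa = _slide_target(starts, n, idx, go_right, bar_lo, bar_hi, N, k)
            starts[idx] = pa
            if record:
                if n_ev >= ev_cap:
                    return STATUS_EVENT_OVERFLOW, n_ev, n, t
                ev_t[n_ev] = t
                ev_kind[n_ev] = EV_SLIDE
                ev_pb[n_ev] = pb
                ev_pa[n_ev] = pa
                n_ev += 1
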