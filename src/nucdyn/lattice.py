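"""Lattice state, kinetic parameters, and the elementary kinetic moves.

The DNA is a linear lattice of ``N`` base pairs; each nucleosome is a hard
rod occupying ``k = 147`` consecutive bp.  Three kinds of event act on the
state:

* adsorption at rate ``k_on`` per eligible start position (a start is
  eligible when its whole footprint is empty, outside any hard barrier, and
  not flagged forbidden);
* removal of the nucleosome at start ``i`` at rate
  ``k0_off · exp(V_i + V_a)`` — with ``k0_off = k_on`` this satisfies the
  Boltzmann condition ``k_on / r_i = exp(-V_i)`` when the active shift
  ``V_a`` is zero, and models ATP-driven eviction when ``V_a > 0``;
* active sliding at rate ``k_slide`` per nucleosome: the nucleosome moves in
  a uniformly chosen direction until it contacts the nearest obstacle
  (neighbour, fixed nucleosome, hard barrier, or lattice end), independent of
  the sequence potential.

The functions here are the readable single-step reference implementation;
:mod:`nucdyn._kernel` reimplements the same moves as a compiled loop for
production ensembles, and the two are cross-checked against the exact
master-equation oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .barriers import BarrierSpec
from .tracks import PotentialTrack

__all__ = [
    "KineticParams",
    "LatticeState",
    "eligible_adsorption_starts",
    "off_rate",
    "execute_slide",
    "apply_fixed_nucleosome",
    "coverage_from_starts",
]


@dataclass(frozen=True)
class KineticParams:
    """Kinetic rates and geometry of the nucleosome model.

    Attributes
    ----------
    k_on
        Adsorption rate (s⁻¹) per eligible start position.
    k_slide
        Active slide-to-contact rate (s⁻¹) per mobile nucleosome.
    active_shift
        V_a (k_BT, ≥ 0): uniform upward shift of the binding potential in the
        off-rate, representing ATP-driven eviction.  0 → purely thermal.
    k0_off
        Base off-rate scale (s⁻¹); defaults to ``k_on`` as required by the
        Boltzmann condition.
    footprint_k
        Nucleosome footprint in bp (147 for a canonical nucleosome).
    """

    k_on: float = 0.06
    k_slide: float = 0.1
    active_shift: float = 0.0
    k0_off: float | None = None
    footprint_k: int = 147

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_slide < 0:
            raise ValueError("rates must be nonnegative")
        if self.active_shift < 0:
            raise ValueError("active_shift (V_a) must be >= 0")
        if self.footprint_k < 1:
            raise ValueError("footprint_k must be >= 1")
        if self.k0_off is not None and self.k0_off < 0:
            raise ValueError("k0_off must be nonnegative")

    @property
    def off_scale(self) -> float:
        return self.k_on if self.k0_off is None else self.k0_off

    def with_shift(self, active_shift: float) -> "KineticParams":
        return replace(self, active_shift=active_shift)


@dataclass
class LatticeState:
    """Non-overlapping nucleosome start positions on an N-bp lattice."""

    length_bp: int
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    barrier: BarrierSpec = field(default_factory=BarrierSpec)
    tss_offset: int = 0
    footprint_k: int = 147
    fixed_start: int | None = None  # absolute start of an immobile nucleosome

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)

    def validate(self) -> None:
        """Raise if any hard-core or barrier invariant is violated."""
        k = self.footprint_k
        s = self.starts
        if s.size and (np.diff(s) < k).any():
            raise ValueError("overlapping nucleosomes")
        if s.size and (s[0] < 0 or s[-1] > self.length_bp - k):
            raise ValueError("nucleosome outside lattice")
        if self.barrier.kind == "hard":
            lo, hi = self.barrier.absolute_interval(self.tss_offset)
            if any(start + k > lo and start <= hi for start in s):
                raise ValueError("nucleosome footprint intersects hard barrier")
        if self.fixed_start is not None and self.fixed_start not in s:
            raise ValueError("fixed nucleosome missing from starts")

    @property
    def n_nucleosomes(self) -> int:
        return int(self.starts.size)

    def coverage(self) -> np.ndarray:
        return coverage_from_starts(self.starts, self.length_bp, self.footprint_k)

    def hard_interval(self) -> tuple[int, int] | None:
        if self.barrier.kind != "hard":
            return None
        return self.barrier.absolute_interval(self.tss_offset)

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.length_bp,
            self.starts.copy(),
            self.barrier,
            self.tss_offset,
            self.footprint_k,
            self.fixed_start,
        )


def coverage_from_starts(starts: np.ndarray, length_bp: int, k: int) -> np.ndarray:
    """0/1 per-bp coverage indicator of a set of rod start positions."""
    cov = np.zeros(length_bp, dtype=np.float64)
    for s in np.asarray(starts, dtype=np.int64):
        cov[s : s + k] = 1.0
    return cov


def eligible_adsorption_starts(
    state: LatticeState, track: PotentialTrack | None = None
) -> np.ndarray:
    """Start positions where a new nucleosome can adsorb.

    A position ``i`` is eligible when the footprint ``[i, i+k)`` lies inside
    the lattice, overlaps no existing nucleosome or hard barrier, and is not
    flagged forbidden in the track.
    """
    n, k = state.length_bp, state.footprint_k
    n_pos = n - k + 1
    if n_pos <= 0:
        return np.empty(0, dtype=np.int64)
    free = np.ones(n, dtype=bool)
    for s in state.starts:
        free[s : s + k] = False
    hard = state.hard_interval()
    if hard is not None:
        lo, hi = hard
        free[max(lo, 0) : hi + 1] = False
    # a start is eligible iff the k bp of its footprint are all free
    run = np.cumsum(np.concatenate(([0], free.astype(np.int64))))
    ok = (run[k:] - run[:-k]) == k
    if track is not None:
        ok &= ~track.forbidden[:n_pos]
    return np.flatnonzero(ok).astype(np.int64)


def off_rate(
    i: int,
    track: PotentialTrack,
    params: KineticParams,
    active: bool = True,
    state: LatticeState | None = None,
) -> float:
    """Removal rate of the nucleosome starting at absolute position ``i``.

    Thermal: ``k0_off · exp(V_i)`` (Boltzmann condition with the adsorption
    rate).  Active: the potential is shifted up by ``V_a`` so the rate is
    ``k0_off · exp(V_i + V_a)``.
    """
    if state is not None and state.fixed_start == i:
        raise ValueError("fixed barrier nucleosome cannot be removed")
    v = track.values[i]
    if not np.isfinite(v):
        raise ValueError(f"off_rate requested at forbidden position {i}")
    shift = params.active_shift if active else 0.0
    return params.off_scale * float(np.exp(v + shift))


def execute_slide(
    state: LatticeState, nucleosome_index: int, direction: str
) -> LatticeState:
    """Slide one nucleosome to contact with the nearest obstacle.

    The move is sequence-independent: the nucleosome jumps in a single event
    to the farthest position in ``direction`` at which it abuts a neighbour,
    a fixed nucleosome, a hard-barrier interval, or the lattice end.  A
    blocked slide returns an unchanged copy (the event is still consumed by
    the caller).
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    new = state.copy()
    s = new.starts
    k = new.footprint_k
    cur = int(s[nucleosome_index])
    if new.fixed_start is not None and cur == new.fixed_start:
        return new  # immobile barrier nucleosome: no-op
    hard = new.hard_interval()
    if direction == "right":
        limit = new.length_bp
        if nucleosome_index + 1 < len(s):
            limit = int(s[nucleosome_index + 1])
        if hard is not None and hard[0] >= cur + k:
            limit = min(limit, hard[0])
        target = limit - k
    else:
        limit = 0
        if nucleosome_index > 0:
            limit = int(s[nucleosome_index - 1]) + k
        if hard is not None and hard[1] < cur:
            limit = max(limit, hard[1] + 1)
        target = limit
    s[nucleosome_index] = target
    return new


def apply_fixed_nucleosome(state: LatticeState, spec: BarrierSpec) -> LatticeState:
    """Install a permanent, immobile nucleosome as the barrier.

    The fixed nucleosome is a regular member of ``starts`` for hard-core
    exclusion but is excluded from removal and sliding.
    """
    if spec.kind != "fixed_nucleosome":
        raise ValueError("apply_fixed_nucleosome requires kind='fixed_nucleosome'")
    pos = spec.fixed_start_j + state.tss_offset
    k = state.footprint_k
    if pos < 0 or pos > state.length_bp - k:
        raise ValueError("fixed nucleosome footprint outside lattice")
    for s in state.starts:
        if s < pos + k and s + k > pos:
            raise ValueError("fixed nucleosome overlaps an existing nucleosome")
    new = state.copy()
    new.starts = np.sort(np.append(new.starts, pos))
    new.barrier = spec
    new.fixed_start = pos
    new.validate()
    return new
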