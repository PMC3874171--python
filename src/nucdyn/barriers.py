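"""Nucleosome-free-region barrier models.

Near most transcription start sites there is a nucleosome-free region (NFR)
whose molecular origin is uncertain.  Three idealizations are supported:

* **hard** — an absolute exclusion zone (e.g. a tightly bound non-histone
  protein): no nucleosome footprint may intersect it and no nucleosome may
  slide across it;
* **soft** — a linear energy ramp ``V(j) = m·j`` over the barrier interval
  (default slope ``m = -13/150`` k_BT/bp, rising from ~0.087 k_BT at j = -1
  to +13 k_BT at j = -150): nucleosomes can be pushed over it but are rapidly
  evicted inside it;
* **fixed_nucleosome** — a permanently positioned, immobile nucleosome acting
  as a steric barrier.

All intervals are in TSS-relative coordinates ``j`` with the default barrier
occupying ``j ∈ [-150, -1]``, immediately upstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import FORBIDDEN, PotentialTrack

__all__ = [
    "BarrierSpec",
    "apply_soft_barrier",
    "apply_hard_barrier",
    "forbidden_start_interval",
]

DEFAULT_SOFT_SLOPE = -13.0 / 150.0


@dataclass(frozen=True)
class BarrierSpec:
    """Specification of the TSS barrier.

    ``start_j``/``end_j`` delimit the (closed) barrier interval in
    TSS-relative coordinates; ``slope_m`` applies to soft barriers only and
    ``fixed_start_j`` to fixed-nucleosome barriers only.
    """

    kind: str = "none"
    start_j: int = -150
    end_j: int = -1
    slope_m: float = DEFAULT_SOFT_SLOPE
    fixed_start_j: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "hard", "soft", "fixed_nucleosome"):
            raise ValueError(f"unknown barrier kind {self.kind!r}")
        if self.kind in ("hard", "soft") and self.end_j < self.start_j:
            raise ValueError("barrier interval is empty (end_j < start_j)")
        if self.kind == "fixed_nucleosome" and self.fixed_start_j is None:
            raise ValueError("fixed_nucleosome barrier requires fixed_start_j")

    @property
    def length(self) -> int:
        return self.end_j - self.start_j + 1

    def absolute_interval(self, tss_offset: int) -> tuple[int, int]:
        """Closed absolute-coordinate interval [lo, hi] of the barrier."""
        return self.start_j + tss_offset, self.end_j + tss_offset


def _check_interval(track: PotentialTrack, spec: BarrierSpec) -> tuple[int, int]:
    lo, hi = spec.absolute_interval(track.tss_offset)
    if lo < 0 or hi >= track.length_bp:
        raise ValueError(
            f"barrier interval j∈[{spec.start_j},{spec.end_j}] maps to "
            f"[{lo},{hi}], outside the {track.length_bp}-bp lattice"
        )
    return lo, hi


def apply_soft_barrier(track: PotentialTrack, spec: BarrierSpec) -> PotentialTrack:
    """Replace the potential inside the barrier interval by the ramp m·j.

    Positions outside the interval are untouched (the operation is local and
    idempotent).
    """
    if spec.kind != "soft":
        raise ValueError("apply_soft_barrier requires a soft BarrierSpec")
    lo, hi = _check_interval(track, spec)
    out = track.copy()
    j = np.arange(spec.start_j, spec.end_j + 1, dtype=float)
    out.values[lo : hi + 1] = spec.slope_m * j
    return out


def forbidden_start_interval(spec: BarrierSpec, footprint_k: int) -> tuple[int, int]:
    """TSS-relative start positions whose footprint intersects a hard barrier.

    A footprint ``[j, j+k)`` intersects ``[start_j, end_j]`` exactly when
    ``j ∈ [start_j - k + 1, end_j]``.
    """
    return spec.start_j - footprint_k + 1, spec.end_j


def apply_hard_barrier(
    track: PotentialTrack, spec: BarrierSpec, footprint_k: int = 147
) -> PotentialTrack:
    """Flag as forbidden every start whose footprint would touch the barrier.

    The flagged track makes the equilibrium oracle exact (activity 0 inside
    the barrier); the simulator additionally blocks sliding across the
    interval geometrically.
    """
    if spec.kind != "hard":
        raise ValueError("apply_hard_barrier requires a hard BarrierSpec")
    _check_interval(track, spec)
    out = track.copy()
    lo_j, hi_j = forbidden_start_interval(spec, footprint_k)
    lo = max(0, lo_j + track.tss_offset)
    hi = min(track.length_bp - 1, hi_j + track.tss_offset)
    if hi >= lo:
        out.values[lo : hi + 1] = FORBIDDEN
    return out
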