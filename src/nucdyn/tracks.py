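"""Per-base-pair nucleosome binding-potential tracks.

A :class:`PotentialTrack` stores, for every base pair ``i`` of an ``N``-bp
lattice, the binding energy ``V_i`` (in units of k_BT) of a nucleosome whose
footprint *starts* at ``i``.  Coordinates come in two frames:

* absolute: ``i`` in ``[0, length_bp)``;
* TSS-relative: ``j = i - tss_offset``, with the transcription start site at
  ``j = 0``.

Start positions that are absolutely disallowed (e.g. inside a hard barrier)
are flagged *forbidden* and stored as ``+inf``: the Boltzmann activity
``exp(-V)`` of such a start is exactly zero and the simulator never proposes
adsorption there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PotentialTrack", "uniform_potential", "potential_from_probability"]

FORBIDDEN = np.inf


@dataclass
class PotentialTrack:
    """Binding energy per possible nucleosome start position.

    Parameters
    ----------
    values
        Array of length ``length_bp``; ``values[i]`` is the energy (k_BT) of a
        nucleosome starting at absolute position ``i``.  ``+inf`` marks a
        forbidden start.
    tss_offset
        Absolute index of the base pair defined as TSS position ``j = 0``.
    """

    values: np.ndarray
    tss_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("track values must be a non-empty 1-D array")
        bad = np.isnan(self.values) | np.isneginf(self.values)
        if bad.any():
            raise ValueError(
                f"track contains non-finite, non-forbidden values at index "
                f"{int(np.flatnonzero(bad)[0])}"
            )

    @property
    def length_bp(self) -> int:
        return int(self.values.size)

    @property
    def forbidden(self) -> np.ndarray:
        """Boolean mask of forbidden start positions."""
        return np.isposinf(self.values)

    @property
    def mean_level(self) -> float:
        """Mean binding energy over allowed starts (the track's V̄)."""
        allowed = ~self.forbidden
        return float(self.values[allowed].mean())

    def to_relative(self, i: int | np.ndarray) -> int | np.ndarray:
        return i - self.tss_offset

    def to_absolute(self, j: int | np.ndarray) -> int | np.ndarray:
        return j + self.tss_offset

    def copy(self) -> "PotentialTrack":
        return PotentialTrack(self.values.copy(), self.tss_offset)


def uniform_potential(length_bp: int, v0: float, tss_offset: int = 0) -> PotentialTrack:
    """Homogeneous track: every start position has energy ``v0`` k_BT."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if not np.isfinite(v0):
        raise ValueError("uniform potential level must be finite")
    return PotentialTrack(np.full(length_bp, float(v0)), tss_offset)


def potential_from_probability(
    probabilities: np.ndarray,
    mean_level: float,
    tss_offset: int = 0,
    floor: float | None = None,
) -> PotentialTrack:
    """Convert a nucleosome start-probability track into binding energies.

    At low nucleosome density the start probability is proportional to the
    Boltzmann weight, ``P_i ∝ exp(-V_i)``, so ``V_i = -ln(P_i) + C`` up to a
    constant.  ``C`` is fixed by requiring ``mean(V_i) = mean_level`` — the
    same convention used to anchor sequence models to the measured average
    nucleosome binding free energy.

    Parameters
    ----------
    probabilities
        Positive per-bp start probabilities (any positive scale).
    mean_level
        Target mean binding energy V̄ in k_BT (typically negative).
    floor
        If given, probabilities below ``floor`` are raised to it before the
        log.  Without a floor, nonpositive entries are an error.
    """
    p = np.asarray(probabilities, dtype=float).copy()
    if not np.isfinite(mean_level):
        raise ValueError("mean_level must be finite")
    if floor is not None:
        if floor <= 0:
            raise ValueError("floor must be positive")
        p = np.maximum(p, floor)
    bad = ~(p > 0) | ~np.isfinite(p)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"nonpositive probability at index {idx}; pass an explicit floor "
            "to clamp near-zero entries"
        )
    v = -np.log(p)
    v += mean_level - v.mean()
    return PotentialTrack(v, tss_offset)
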