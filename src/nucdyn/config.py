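"""Structured run configuration (YAML) with schema validation.

A config fully specifies a simulation campaign: lattice geometry, potential
source, barrier, kinetic rates, horizon/snapshots/replicas, and the
exposure observation window.  Unknown keys and physically inconsistent
settings are rejected with the offending key path in the message.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .barriers import BarrierSpec
from .lattice import KineticParams
from .synthetic import synthetic_gene_potential
from .tracks import PotentialTrack, uniform_potential

__all__ = ["Config", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LatticeConfig(_Strict):
    length_bp: int = Field(gt=0)
    tss_offset: int = Field(default=0, ge=0)


class PotentialConfig(_Strict):
    source: Literal["uniform", "file", "synthetic"] = "uniform"
    v0: float = -7.0  # uniform level, k_BT
    path: Optional[str] = None  # bedGraph/wiggle file for source=file
    # synthetic-generator parameters
    sd: float = Field(default=1.5, ge=0)
    corr_length_bp: float = Field(default=20.0, ge=1)
    periodic_amp: float = 0.3
    period_bp: float = Field(default=10.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.source == "file" and not self.path:
            raise ValueError("potential.path required when source=file")
        return self


class BarrierConfig(_Strict):
    kind: Literal["none", "hard", "soft", "fixed_nucleosome"] = "none"
    start_j: int = -150
    end_j: int = -1
    slope_m: float = -13.0 / 150.0
    fixed_start_j: Optional[int] = None

    def to_spec(self) -> BarrierSpec:
        return BarrierSpec(
            kind=self.kind,
            start_j=self.start_j,
            end_j=self.end_j,
            slope_m=self.slope_m,
            fixed_start_j=self.fixed_start_j,
        )


class RatesConfig(_Strict):
    k_on: float = Field(default=0.06, ge=0)
    k_slide: float = Field(default=0.1, ge=0)
    active_shift: float = Field(default=0.0, ge=0)
    k0_off: Optional[float] = Field(default=None, ge=0)
    footprint_k: int = Field(default=147, ge=1)

    def to_params(self) -> KineticParams:
        return KineticParams(
            k_on=self.k_on,
            k_slide=self.k_slide,
            active_shift=self.active_shift,
            k0_off=self.k0_off,
            footprint_k=self.footprint_k,
        )


class RunConfig(_Strict):
    t_end: float = Field(default=3600.0, gt=0)
    snapshot_times: list[float] = Field(default_factory=list)
    replicas: int = Field(default=100, ge=1)
    base_seed: int = 0
    record_events: bool = True


class ExposureConfig(_Strict):
    site_length: int = Field(default=10, ge=1)
    window: tuple[float, float] = (1800.0, 3600.0)
    n_sites: Optional[int] = None


class Config(_Strict):
    lattice: LatticeConfig
    potential: PotentialConfig = PotentialConfig()
    barrier: BarrierConfig = BarrierConfig()
    rates: RatesConfig = RatesConfig()
    run: RunConfig = RunConfig()
    exposure: ExposureConfig = ExposureConfig()

    @model_validator(mode="after")
    def _physical(self):
        n = self.lattice.length_bp
        off = self.lattice.tss_offset
        if self.barrier.kind in ("hard", "soft"):
            lo = self.barrier.start_j + off
            hi = self.barrier.end_j + off
            if lo < 0 or hi >= n:
                raise ValueError(
                    f"barrier: interval [{self.barrier.start_j}, {self.barrier.end_j}] "
                    f"falls outside the lattice for tss_offset={off}"
                )
        w1, w2 = self.exposure.window
        if w1 >= w2:
            raise ValueError("exposure.window: start must precede end")
        if w2 > self.run.t_end:
            raise ValueError("exposure.window: end exceeds run.t_end")
        if self.rates.footprint_k > n:
            raise ValueError("rates.footprint_k exceeds lattice length")
        return self

    # ---- realization helpers --------------------------------------------

    def build_track(self) -> PotentialTrack:
        from . import trackio
        from .barriers import apply_hard_barrier, apply_soft_barrier

        pot = self.potential
        off = self.lattice.tss_offset
        if pot.source == "uniform":
            track = uniform_potential(self.lattice.length_bp, pot.v0, off)
        elif pot.source == "synthetic":
            track = synthetic_gene_potential(
                self.lattice.length_bp,
                mean_level=pot.v0,
                sd=pot.sd,
                corr_length_bp=pot.corr_length_bp,
                periodic_amp=pot.periodic_amp,
                period_bp=pot.period_bp,
                seed=pot.seed,
                tss_offset=off,
            )
        else:
            path = Path(pot.path)
            reader = trackio.read_wiggle if path.suffix in (".wig", ".wiggle") else trackio.read_bedgraph
            track = reader(path)
        spec = self.barrier.to_spec()
        if spec.kind == "soft":
            track = apply_soft_barrier(track, spec)
        elif spec.kind == "hard":
            track = apply_hard_barrier(track, spec, self.rates.footprint_k)
        return track

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path) -> Config:
    """Load and validate a YAML config; raises ConfigError with key paths."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return Config.model_validate(raw)
    except ValidationError as err:
        lines = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError("invalid config:\n  " + "\n  ".join(lines)) from err
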