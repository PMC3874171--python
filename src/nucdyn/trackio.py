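"""Plain-text track and table I/O.

Potential tracks and occupancy profiles are exchanged as bedGraph (0-based
half-open intervals) or fixed-step wiggle.  The TSS-relative frame is
preserved through a ``# tss_offset=<int>`` header comment; forbidden start
positions are serialized as a companion BED interval file (bedGraph cannot
carry infinities).  Event logs go to TSV with JSON metadata in ``##``
header lines; ``.gz`` suffixes trigger gzip compression transparently.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np

from .tracks import FORBIDDEN, PotentialTrack

__all__ = [
    "write_bedgraph",
    "read_bedgraph",
    "write_wiggle",
    "read_wiggle",
    "write_forbidden_bed",
    "read_forbidden_bed",
    "write_events_tsv",
    "read_events_tsv",
]

CHROM = "track"


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _runs(values: np.ndarray):
    """Yield (start, end, value) runs of equal consecutive values."""
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    bounds = np.concatenate(([0], change, [values.size]))
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        yield int(lo), int(hi), values[lo]


def write_bedgraph(
    values, path, tss_offset: int = 0, chrom: str = CHROM, header: dict | None = None
) -> None:
    """Write per-bp values as bedGraph; forbidden positions become 'nan'."""
    if isinstance(values, PotentialTrack):
        tss_offset = values.tss_offset
        values = values.values
    values = np.asarray(values, dtype=float)
    with _open(path, "w") as fh:
        fh.write(f"# tss_offset={tss_offset}\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        out = np.where(np.isposinf(values), np.nan, values)
        for lo, hi, v in _runs(out):
            sval = "nan" if np.isnan(v) else repr(float(v))
            fh.write(f"{chrom}\t{lo}\t{hi}\t{sval}\n")


def read_bedgraph(path) -> PotentialTrack:
    """Read a bedGraph written by :func:`write_bedgraph` ('nan' → forbidden)."""
    tss_offset = 0
    rows = []
    with _open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("tss_offset="):
                    tss_offset = int(body.split("=", 1)[1])
                continue
            if line.startswith(("track", "browser")) and "\t" not in line:
                continue
            _, lo, hi, val = line.split("\t")
            rows.append((int(lo), int(hi), float(val)))
    if not rows:
        raise ValueError(f"no intervals in {path}")
    length = max(hi for _, hi, _ in rows)
    values = np.full(length, np.nan)
    for lo, hi, v in rows:
        values[lo:hi] = v
    values = np.where(np.isnan(values), FORBIDDEN, values)
    return PotentialTrack(values, tss_offset)


def write_wiggle(values, path, tss_offset: int = 0, chrom: str = CHROM) -> None:
    """Fixed-step wiggle (step 1); forbidden positions become 'nan'."""
    if isinstance(values, PotentialTrack):
        tss_offset = values.tss_offset
        values = values.values
    values = np.asarray(values, dtype=float)
    with _open(path, "w") as fh:
        fh.write(f"# tss_offset={tss_offset}\n")
        fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
        for v in values:
            fh.write("nan\n" if np.isposinf(v) else repr(float(v)) + "\n")


def read_wiggle(path) -> PotentialTrack:
    tss_offset = 0
    vals = []
    with _open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("fixedStep", "track")):
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("tss_offset="):
                    tss_offset = int(body.split("=", 1)[1])
                continue
            vals.append(float(line))
    values = np.asarray(vals)
    values = np.where(np.isnan(values), FORBIDDEN, values)
    return PotentialTrack(values, tss_offset)


def write_forbidden_bed(track: PotentialTrack, path, chrom: str = CHROM) -> None:
    """Forbidden start positions as BED intervals (companion to bedGraph)."""
    mask = track.forbidden
    with _open(path, "w") as fh:
        fh.write(f"# tss_offset={track.tss_offset}\n")
        if mask.any():
            for lo, hi, v in _runs(mask.astype(np.int8)):
                if v:
                    fh.write(f"{chrom}\t{lo}\t{hi}\tforbidden\n")


def read_forbidden_bed(path) -> list[tuple[int, int]]:
    out = []
    with _open(path, "r") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            _, lo, hi, *_ = line.split("\t")
            out.append((int(lo), int(hi)))
    return out


def write_events_tsv(log, path) -> None:
    """One replica's event log as TSV with JSON metadata header lines."""
    meta = dict(
        replica_id=log.replica_id,
        seed=log.seed,
        length_bp=log.length_bp,
        footprint_k=log.footprint_k,
        t_start=log.t_start,
        t_end=log.t_end,
        tss_offset=log.tss_offset,
        fixed_start=log.fixed_start,
        initial_starts=[int(s) for s in log.initial_starts],
        snapshot_times=[float(t) for t in log.snapshot_times],
        snapshots=[[int(s) for s in snap] for snap in log.snapshots],
    )
    kind_name = {0: "adsorb", 1: "desorb", 2: "slide"}
    with _open(path, "w") as fh:
        fh.write("## " + json.dumps(meta) + "\n")
        fh.write("t\tkind\tpos_before\tpos_after\n")
        for m in range(log.n_events):
            fh.write(
                f"{float(log.times[m])!r}\t{kind_name[int(log.kinds[m])]}\t"
                f"{int(log.pos_before[m])}\t{int(log.pos_after[m])}\n"
            )


def read_events_tsv(path):
    from .simulate import EventLog

    kind_code = {"adsorb": 0, "desorb": 1, "slide": 2}
    meta = None
    times, kinds, pb, pa = [], [], [], []
    with _open(path, "r") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                meta = json.loads(line[2:].strip())
                continue
            if not line or line.startswith("t\t"):
                continue
            t, kind, b, a = line.split("\t")
            times.append(float(t))
            kinds.append(kind_code[kind])
            pb.append(int(b))
            pa.append(int(a))
    if meta is None:
        raise ValueError(f"missing metadata header in {path}")
    return EventLog(
        replica_id=meta["replica_id"],
        seed=meta["seed"],
        length_bp=meta["length_bp"],
        footprint_k=meta["footprint_k"],
        t_start=meta["t_start"],
        t_end=meta["t_end"],
        times=np.asarray(times),
        kinds=np.asarray(kinds, dtype=np.int8),
        pos_before=np.asarray(pb, dtype=np.int64),
        pos_after=np.asarray(pa, dtype=np.int64),
        snapshot_times=np.asarray(meta["snapshot_times"]),
        snapshots=[np.asarray(s, dtype=np.int64) for s in meta["snapshots"]],
        initial_starts=np.asarray(meta["initial_starts"], dtype=np.int64),
        final_starts=np.empty(0, dtype=np.int64),
        events_recorded=True,
        tss_offset=meta["tss_offset"],
        fixed_start=meta["fixed_start"],
    )
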