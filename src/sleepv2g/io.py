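"""Readers and writers for the pipeline's on-disk dialects.

All coordinate-base conversion happens here and nowhere else: variant tables
carry 1-based positions, BED and ibed files 0-based half-open intervals, and
the in-memory objects are 0-based half-open except ProxyVariant.pos which
stays 1-based (converted at use sites via ``pos0``).

Dialects
--------
- sentinels/proxies TSV: columns signal_id, locus_id, rsid, chrom,
  pos_1based, r2.  The sentinel row of a signal is the one whose rsid equals
  the signal_id (written with r2 = 1).
- peaks BED: chrom, start, end, name=peak_id.
- baits BED: chrom, start, end, name="bait_id|gene1,gene2|1,0" (coding flags
  aligned with genes).
- interactions ibed-style TSV: bait_chrom, bait_start, bait_end, bait_id,
  oe_chrom, oe_start, oe_end, score, resolution.
- expression TSV: gene, tpm[, percentile]; missing percentiles are derived
  as TPM percent ranks.
- DAM monitor file: tab-delimited rows of index, date, time, status, then 32
  per-channel counts (one row per minute).
- zebrafish tracking CSV: larva_id, group, minute_index, movement_sec.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from sleepv2g.fly import ActivityTrace
from sleepv2g.restriction import FragmentMap
from sleepv2g.v2g import (
    BaitedPromoter,
    ExpressionRecord,
    Interaction,
    Peak,
    ProxyVariant,
    SentinelSignal,
    attach_percentiles,
)
from sleepv2g.zebrafish import ZfTrace


def pos_1to0(pos: int) -> int:
    """1-based position -> 0-based coordinate."""
    if pos < 1:
        raise ValueError("1-based positions must be >= 1")
    return pos - 1


def pos_0to1(pos: int) -> int:
    """0-based coordinate -> 1-based position."""
    if pos < 0:
        raise ValueError("0-based positions must be >= 0")
    return pos + 1


class FormatError(ValueError):
    """Malformed input row; message carries the 1-based line number."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def iter_fasta(path) -> Iterator[tuple[str, str]]:
    """Stream (name, sequence) records from a plain or gzipped FASTA."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def read_fasta(path) -> dict[str, str]:
    return dict(iter_fasta(path))


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- BED

def read_bed(path, n_fields: int = 4) -> pd.DataFrame:
    """Read a BED file, validating coordinates row by row."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min(n_fields, 3):
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            name = parts[3] if len(parts) > 3 else f"row{lineno}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(records: Iterable[tuple], path) -> None:
    """Write (chrom, start, end, name) records as BED."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def write_fragment_map_bed(fmap: FragmentMap, path) -> None:
    write_bed(fmap.to_records(), path)


def read_peaks_bed(path) -> list[Peak]:
    df = read_bed(path)
    return [Peak(r.name, r.chrom, r.start, r.end) for r in df.itertuples(index=False)]


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    write_bed(((p.chrom, p.start, p.end, p.peak_id) for p in peaks), path)


def read_baits_bed(path) -> list[BaitedPromoter]:
    df = read_bed(path)
    baits = []
    for lineno, r in enumerate(df.itertuples(index=False), start=1):
        parts = r.name.split("|")
        if len(parts) != 3:
            raise FormatError(
                f"{path}: bait name {r.name!r} not in 'bait_id|genes|coding' form"
            )
        bait_id, genes_s, flags_s = parts
        genes = genes_s.split(",")
        flags = [f == "1" for f in flags_s.split(",")]
        baits.append(BaitedPromoter(bait_id, r.chrom, r.start, r.end, genes, flags))
    return baits


def write_baits_bed(baits: Sequence[BaitedPromoter], path) -> None:
    def name(b: BaitedPromoter) -> str:
        return "|".join(
            [b.bait_id, ",".join(b.gene_names), ",".join("1" if f else "0" for f in b.coding_flags)]
        )

    write_bed(((b.chrom, b.start, b.end, name(b)) for b in baits), path)


# ---------------------------------------------------------------- variant tables

PROXY_COLUMNS = ["signal_id", "locus_id", "rsid", "chrom", "pos_1based", "r2"]


def read_proxy_table(path) -> tuple[list[SentinelSignal], pd.DataFrame]:
    """Read the sentinels/proxies TSV.

    Returns the sentinel list and an LD-record frame with columns
    (sentinel_id, rsid, chrom, pos, r2) ready for
    :func:`sleepv2g.v2g.expand_proxies`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in PROXY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = df.index[(df["pos_1based"] < 1) | ~df["r2"].between(0, 1)]
    if len(bad):
        raise FormatError(f"{path}: line {int(bad[0]) + 2}: invalid pos or r2")
    sentinels = []
    for r in df[df["rsid"] == df["signal_id"]].itertuples(index=False):
        sentinels.append(
            SentinelSignal(r.rsid, r.chrom, int(r.pos_1based), r.locus_id, r.signal_id)
        )
    ld = df[df["rsid"] != df["signal_id"]].rename(
        columns={"signal_id": "sentinel_id", "pos_1based": "pos"}
    )[["sentinel_id", "rsid", "chrom", "pos", "r2"]]
    return sentinels, ld.reset_index(drop=True)


def write_proxy_table(
    sentinels: Sequence[SentinelSignal], ld: pd.DataFrame, path
) -> None:
    rows = [
        {
            "signal_id": s.signal_id,
            "locus_id": s.locus_id,
            "rsid": s.rsid,
            "chrom": s.chrom,
            "pos_1based": s.pos,
            "r2": 1.0,
        }
        for s in sentinels
    ]
    for r in ld.itertuples(index=False):
        rows.append(
            {
                "signal_id": r.sentinel_id,
                "locus_id": next(s.locus_id for s in sentinels if s.signal_id == r.sentinel_id),
                "rsid": r.rsid,
                "chrom": r.chrom,
                "pos_1based": int(r.pos),
                "r2": float(r.r2),
            }
        )
    pd.DataFrame(rows, columns=PROXY_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------- interactions (ibed)

IBED_COLUMNS = [
    "bait_chrom", "bait_start", "bait_end", "bait_id",
    "oe_chrom", "oe_start", "oe_end", "score", "resolution",
]


def read_interactions(path) -> list[Interaction]:
    df = pd.read_csv(path, sep="\t", dtype={"bait_chrom": str, "oe_chrom": str})
    missing = [c for c in IBED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for i, r in enumerate(df.itertuples(index=False)):
        if r.oe_start < 0 or r.oe_start >= r.oe_end:
            raise FormatError(f"{path}: line {i + 2}: invalid other-end interval")
        out.append(
            Interaction(r.bait_id, r.oe_chrom, int(r.oe_start), int(r.oe_end),
                        float(r.score), r.resolution)
        )
    return out


def write_interactions(
    interactions: Sequence[Interaction], baits: Sequence[BaitedPromoter], path
) -> None:
    bait_by_id = {b.bait_id: b for b in baits}
    rows = []
    for ia in interactions:
        b = bait_by_id[ia.bait_id]
        rows.append(
            {
                "bait_chrom": b.chrom, "bait_start": b.start, "bait_end": b.end,
                "bait_id": ia.bait_id, "oe_chrom": ia.other_chrom,
                "oe_start": ia.other_start, "oe_end": ia.other_end,
                "score": ia.score, "resolution": ia.resolution,
            }
        )
    pd.DataFrame(rows, columns=IBED_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------- expression

def read_expression(path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "tpm" not in df.columns:
        raise FormatError(f"{path}: expression table needs 'gene' and 'tpm' columns")
    if (df["tpm"] < 0).any():
        bad = int(df.index[df["tpm"] < 0][0]) + 2
        raise FormatError(f"{path}: line {bad}: negative TPM")
    if "percentile" in df.columns:
        return [
            ExpressionRecord(r.gene, float(r.tpm), float(r.percentile))
            for r in df.itertuples(index=False)
        ]
    return attach_percentiles(dict(zip(df["gene"], df["tpm"])))


def write_expression(records: Sequence[ExpressionRecord], path) -> None:
    pd.DataFrame(
        [{"gene": e.gene, "tpm": e.tpm, "percentile": e.percentile} for e in records]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------- behavior traces

def read_activity_csv(path, line_map: Mapping[str, str] | None = None) -> list[ActivityTrace]:
    """Long-format activity CSV: animal_id, line, minute_index, counts."""
    df = pd.read_csv(path)
    needed = {"animal_id", "minute_index", "counts"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(needed)}")
    if (df["counts"] < 0).any():
        bad = int(df.index[df["counts"] < 0][0]) + 2
        raise FormatError(f"{path}: line {bad}: negative counts")
    traces = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("minute_index")
        line = (
            str(sub["line"].iloc[0]) if "line" in sub.columns
            else (line_map or {}).get(str(animal_id), "unknown")
        )
        traces.append(ActivityTrace(str(animal_id), line, sub["counts"].to_numpy()))
    return traces


def write_activity_csv(traces: Sequence[ActivityTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "animal_id": t.animal_id,
                "line": t.line,
                "minute_index": np.arange(t.n_minutes),
                "counts": t.counts,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dam_monitor(path) -> np.ndarray:
    """Read a DAM monitor file into a (n_minutes, 32) count matrix.

    Rows are tab-delimited: reading index, date, time, status, six device
    fields, then 32 per-channel counts.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 42:
                raise FormatError(f"{path}:{lineno}: expected 42 fields, got {len(parts)}")
            try:
                rows.append([int(x) for x in parts[10:42]])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer channel counts") from None
    return np.asarray(rows, dtype=np.int64)


def write_dam_monitor(counts: np.ndarray, path, start_minute: int = 0) -> None:
    """Write a (n_minutes, <=32) count matrix as a DAM monitor file."""
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] > 32:
        raise ValueError("counts must be (n_minutes, <=32)")
    full = np.zeros((counts.shape[0], 32), dtype=np.int64)
    full[:, : counts.shape[1]] = counts
    with _open_text(path, "wt") as fh:
        for i, row in enumerate(full):
            minute = start_minute + i
            hh, mm = (minute // 60) % 24, minute % 60
            day = 1 + minute // 1440
            fields = [str(i + 1), f"{day:02d} Jan 00", f"{hh:02d}:{mm:02d}:00", "1"]
            fields += ["0"] * 6 + [str(int(c)) for c in row]
            fh.write("\t".join(fields) + "\n")


def read_tracking_csv(path, clock_start_min: int, lights_on_min: int = 540,
                      lights_off_min: int = 1380) -> list[ZfTrace]:
    """Zebrafish tracking export: larva_id, group, minute_index, movement_sec."""
    df = pd.read_csv(path)
    needed = {"larva_id", "group", "minute_index", "movement_sec"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: need columns {sorted(needed)}")
    bad = df.index[(df["movement_sec"] < 0) | (df["movement_sec"] > 60)]
    if len(bad):
        raise FormatError(f"{path}: line {int(bad[0]) + 2}: movement outside [0, 60]")
    traces = []
    for larva_id, sub in df.groupby("larva_id", sort=True):
        sub = sub.sort_values("minute_index")
        traces.append(
            ZfTrace(str(larva_id), str(sub["group"].iloc[0]),
                    sub["movement_sec"].to_numpy(dtype=float),
                    clock_start_min=clock_start_min,
                    lights_on_min=lights_on_min, lights_off_min=lights_off_min)
        )
    return traces


def write_tracking_csv(traces: Sequence[ZfTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "larva_id": t.larva_id,
                "group": t.group,
                "minute_index": np.arange(t.n_minutes),
                "movement_sec": t.movement_sec,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.4f")
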