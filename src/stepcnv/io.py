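"""Readers and writers for the plain-text interchange formats.

GCN tables are tab-delimited ``chrom  position  value`` files (header
optional, one chromosome per fit unit).  Read positions come from BED3 or
two-column ``chrom  start`` TSV files.  Calls are written both as 0-based
half-open BED and as a TSV that keeps the 1-based inclusive probe indices
of the model space; chain traces are TSV; summaries are JSON.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .gibbs import Chain
from .model import GCNSignal
from .pipeline import PipelineConfig, SegmentCall
from .readdepth import ReadSet

__all__ = [
    "read_gcn_table",
    "write_gcn_table",
    "read_read_positions",
    "write_calls_bed",
    "write_calls_tsv",
    "write_chain_trace",
    "write_summary_json",
    "load_config",
]


def _has_header(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline().split("\t")
    if len(first) < 3:
        return True
    try:
        int(first[1])
        float(first[2])
        return False
    except ValueError:
        return True


def read_gcn_table(path: str | Path) -> list[GCNSignal]:
    """Read a GCN table into one signal per chromosome (file order)."""
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if _has_header(path) else None,
        names=["chrom", "position", "value"],
        dtype={0: str},
    )
    signals = []
    for chrom, grp in df.groupby("chrom", sort=False):
        signals.append(
            GCNSignal(
                grp["position"].to_numpy(np.int64),
                grp["value"].to_numpy(np.float64),
                chrom=str(chrom),
            )
        )
    return signals


def write_gcn_table(signals: GCNSignal | Sequence[GCNSignal], path: str | Path) -> None:
    if isinstance(signals, GCNSignal):
        signals = [signals]
    frames = [
        pd.DataFrame(
            {
                "chrom": sig.chrom or "chr?",
                "position": sig.locations,
                "value": sig.values,
            }
        )
        for sig in signals
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False, header=True)


def read_read_positions(path: str | Path) -> list[ReadSet]:
    """Read BED3 (chrom, start, end) or two-column (chrom, start) read
    positions into one ReadSet per chromosome."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("read-position file needs at least chrom and start columns")
    reads = []
    for chrom, grp in df.groupby(0, sort=False):
        reads.append(ReadSet(str(chrom), grp[1].to_numpy(np.int64)))
    return reads


def write_calls_bed(calls: Sequence[SegmentCall], path: str | Path) -> None:
    """Calls as BED: chrom, start, end (0-based half-open), name, amplitude."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls, 1):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tcnv_{i}\t{c.a_mean:.4f}\n"
            )


def write_calls_tsv(calls: Sequence[SegmentCall], path: str | Path) -> None:
    """Full call table, probe indices 1-based inclusive as in the model."""
    rows = []
    for c in calls:
        row = dataclasses.asdict(c)
        for key in ("a_ci", "s_ci", "e_ci"):
            lo, hi = row.pop(key)
            row[f"{key}_lo"], row[f"{key}_hi"] = lo, hi
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_chain_trace(chain: Chain, path: str | Path) -> None:
    chain.to_frame().to_csv(path, sep="\t", index=False)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_summary_json(payload, path: str | Path) -> None:
    """Summaries/reports as JSON; dataclasses and numpy types are unpacked."""
    with open(path, "w") as fh:
        json.dump(_jsonify(payload), fh, indent=2)
        fh.write("\n")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file with optional ``hp``,
    ``sampler`` and top-level chunking/evidence keys."""
    from .gibbs import SamplerConfig
    from .model import Hyperparameters

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    hp = Hyperparameters(**raw.get("hp", {}))
    sampler = SamplerConfig(**raw.get("sampler", {}))
    kwargs = {
        k: raw[k]
        for k in ("chunk_size", "overlap", "delta", "early_stop")
        if k in raw
    }
    return PipelineConfig(hp=hp, sampler=sampler, **kwargs)
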