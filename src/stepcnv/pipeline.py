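"""Whole-signal orchestration: chunking, per-chunk model selection, and
merging of boundary calls.

Large signals are processed divide-and-conquer: features are sorted per
chromosome, grouped into chunks of consecutive probes (default 1000),
each chunk is fitted independently (model selection over N followed by the
selected model's chain summary), and per-chunk calls are merged.  Chunks
may optionally overlap; duplicated calls in overlap zones are deduplicated
by reciprocal overlap, keeping the higher-confidence one.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evidence import select_n
from .gibbs import SamplerConfig, summarize
from .model import GCNSignal, Hyperparameters

__all__ = [
    "ChunkPlan",
    "SegmentCall",
    "PipelineConfig",
    "make_chunk_plan",
    "run_pipeline",
    "merge_chunk_calls",
    "model_scan_table",
]

logger = logging.getLogger("stepcnv")


@dataclass
class ChunkPlan:
    """Index chunks of one chromosome's signal.

    ``cores`` are half-open 0-based index ranges that partition the probes
    exactly; ``spans`` extend each core by ``overlap`` probes on both sides
    (clipped to the signal) and are what actually gets fitted.
    """

    M: int
    chunk_size: int
    overlap: int
    cores: list[tuple[int, int]] = field(default_factory=list)
    spans: list[tuple[int, int]] = field(default_factory=list)


def make_chunk_plan(M: int, chunk_size: int = 1000, overlap: int = 0) -> ChunkPlan:
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if overlap < 0:
        raise ValueError("overlap must be >= 0")
    cores, spans = [], []
    for start in range(0, M, chunk_size):
        core = (start, min(start + chunk_size, M))
        span = (max(0, start - overlap), min(M, core[1] + overlap))
        cores.append(core)
        spans.append(span)
    return ChunkPlan(M=M, chunk_size=chunk_size, overlap=overlap, cores=cores, spans=spans)


@dataclass
class SegmentCall:
    """One called CNV with genomic coordinates, posterior summaries and
    provenance.  ``start``/``end`` are 0-based half-open bp; ``s_index`` /
    ``e_index`` are 1-based inclusive probe indices on the chromosome."""

    chrom: str
    start: int
    end: int
    a_mean: float
    a_sd: float
    a_ci: tuple[float, float]
    s_index: int
    e_index: int
    s_sd: float
    e_sd: float
    s_ci: tuple[float, float]
    e_ci: tuple[float, float]
    n_selected: int
    seed: int
    config_hash: str
    chunk_id: int = 0

    def confidence(self) -> float:
        """Posterior amplitude |mean| / sd (inf when the sd is zero)."""
        if self.a_sd == 0:
            return float("inf")
        return abs(self.a_mean) / self.a_sd


@dataclass
class PipelineConfig:
    """End-to-end settings: priors, sampler, chunking and evidence."""

    hp: Hyperparameters = field(default_factory=Hyperparameters)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    chunk_size: int = 1000
    overlap: int = 0
    delta: float = 0.01
    early_stop: bool = True

    def digest(self) -> str:
        payload = {
            "hp": {
                k: (v if not isinstance(v, tuple) else [np.asarray(x).tolist() for x in v])
                for k, v in asdict(self.hp).items()
            },
            "sampler": {
                "n_iter": self.sampler.n_iter,
                "burn_in": self.sampler.burn_in,
                "n_chains": self.sampler.n_chains,
                "blocked": self.sampler.blocked,
            },
            "chunk_size": self.chunk_size,
            "overlap": self.overlap,
            "delta": self.delta,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _check_sorted(signal: GCNSignal) -> GCNSignal:
    locs = signal.locations
    order = np.argsort(locs, kind="stable")
    locs_sorted = locs[order]
    dup = locs_sorted[:-1][np.diff(locs_sorted) == 0]
    if len(dup):
        offenders = ", ".join(map(str, np.unique(dup)[:10]))
        raise ValueError(
            f"duplicate positions on {signal.chrom or '?'}: {offenders}"
        )
    if np.array_equal(order, np.arange(len(locs))):
        return signal
    return GCNSignal(locs_sorted, signal.values[order], chrom=signal.chrom)


def run_pipeline(
    signals: GCNSignal | Sequence[GCNSignal],
    config: Optional[PipelineConfig] = None,
) -> tuple[list[SegmentCall], list[dict]]:
    """Fit every chromosome chunk-by-chunk and return merged calls plus
    per-chunk model-scan reports.

    Per chromosome: features are sorted by location (duplicate positions
    are an error), chunked, and each chunk is fitted by Bayes-factor model
    selection over N; the selected model's posterior summary yields one
    call per segment.  Calls from overlapping chunk zones are merged.
    """
    config = config or PipelineConfig()
    if isinstance(signals, GCNSignal):
        signals = [signals]
    seed = config.sampler.resolved_seed()
    digest = config.digest()
    calls: list[SegmentCall] = []
    reports: list[dict] = []

    chunk_id = 0
    for signal in signals:
        signal = _check_sorted(signal)
        chrom = signal.chrom or "chr?"
        plan = make_chunk_plan(signal.M, config.chunk_size, config.overlap)
        seeds = np.random.SeedSequence(seed).spawn(len(plan.spans))
        for (lo, hi), child in zip(plan.spans, seeds):
            sub = GCNSignal(signal.locations[lo:hi], signal.values[lo:hi], chrom=chrom)
            sub_cfg = SamplerConfig(
                n_iter=config.sampler.n_iter,
                burn_in=config.sampler.burn_in,
                seed=int(child.generate_state(1)[0] % (2**31)),
                n_chains=config.sampler.n_chains,
                blocked=config.sampler.blocked,
            )
            best_n, results = select_n(
                sub,
                config.hp,
                sub_cfg,
                delta=config.delta,
                early_stop=config.early_stop,
                keep_chains=True,
            )
            logger.info(
                "chunk %d (%s probes %d-%d): selected N=%d", chunk_id, chrom, lo, hi, best_n
            )
            reports.append(
                {
                    "chunk_id": chunk_id,
                    "chrom": chrom,
                    "probe_lo": lo,
                    "probe_hi": hi,
                    "selected_n": best_n,
                    "scan": [
                        {
                            "n": r.n,
                            "log_evidence": r.log_evidence,
                            "log_bf_vs_null": r.log_bf_vs_null,
                            "selected": r.n == best_n,
                        }
                        for r in results
                    ],
                }
            )
            if best_n > 0:
                chain = next(r.chain for r in results if r.n == best_n)
                summ = summarize(chain)
                for seg in summ.segments:
                    s_glob = seg.s_mode + lo  # 1-based on the chromosome
                    e_glob = seg.e_mode + lo
                    calls.append(
                        SegmentCall(
                            chrom=chrom,
                            start=int(signal.locations[s_glob - 1]),
                            end=int(signal.locations[e_glob - 1]) + 1,
                            a_mean=seg.a_mean,
                            a_sd=seg.a_sd,
                            a_ci=seg.a_ci,
                            s_index=s_glob,
                            e_index=e_glob,
                            s_sd=seg.s_sd,
                            e_sd=seg.e_sd,
                            s_ci=(seg.s_ci[0] + lo, seg.s_ci[1] + lo),
                            e_ci=(seg.e_ci[0] + lo, seg.e_ci[1] + lo),
                            n_selected=best_n,
                            seed=chain.seed,
                            config_hash=digest,
                            chunk_id=chunk_id,
                        )
                    )
            chunk_id += 1
        calls = merge_chunk_calls(calls, plan)
    return calls, reports


def _reciprocal_overlap(c1: SegmentCall, c2: SegmentCall) -> float:
    lo = max(c1.s_index, c2.s_index)
    hi = min(c1.e_index, c2.e_index)
    inter = max(0, hi - lo + 1)
    len1 = c1.e_index - c1.s_index + 1
    len2 = c2.e_index - c2.s_index + 1
    return min(inter / len1, inter / len2)


def merge_chunk_calls(
    calls: Sequence[SegmentCall], plan: Optional[ChunkPlan] = None
) -> list[SegmentCall]:
    """Deduplicate calls reported by more than one chunk.

    Calls from different chunks on the same chromosome with reciprocal
    probe-index overlap >= 50% are considered the same event; the one with
    the higher posterior amplitude confidence (|mean|/sd) is kept.  All
    other calls pass through unchanged.
    """
    kept: list[SegmentCall] = []
    for call in sorted(calls, key=lambda c: (c.chrom, c.s_index, c.e_index)):
        duplicate = False
        for i, prev in enumerate(kept):
            if (
                prev.chrom == call.chrom
                and prev.chunk_id != call.chunk_id
                and _reciprocal_overlap(prev, call) >= 0.5
            ):
                if call.confidence() > prev.confidence():
                    kept[i] = call
                duplicate = True
                break
        if not duplicate:
            kept.append(call)
    return kept


def model_scan_table(reports: Sequence[dict]) -> pd.DataFrame:
    """Flatten per-chunk model-scan reports into one table."""
    rows = []
    for rep in reports:
        for entry in rep["scan"]:
            rows.append(
                {
                    "chunk_id": rep["chunk_id"],
                    "chrom": rep["chrom"],
                    "n": entry["n"],
                    "log_evidence": entry["log_evidence"],
                    "log_bf_vs_null": entry["log_bf_vs_null"],
                    "selected": entry["selected"],
                }
            )
    return pd.DataFrame(rows)
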