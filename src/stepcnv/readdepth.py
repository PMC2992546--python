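"""Read-depth signal construction and depth-related experiments.

Mapped-read start positions are counted in non-overlapping windows tiled
across a region; subtracting the global mean count turns the window counts
into an array-like GCN signal whose segments the Bayesian model can fit.
For clean read-depth data, CNV amplitudes aggregate at multiples of the
haploid mean depth c, so a finite amplitude prior over {-c, +c, +2c} is
provided.  A coverage-downsampling experiment quantifies how breakpoint
uncertainty grows as sequencing depth falls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gibbs import SamplerConfig, fit_model, summarize
from .model import GCNSignal, Hyperparameters

__all__ = [
    "ReadSet",
    "DepthSignal",
    "window_counts",
    "center",
    "discrete_amplitude_prior",
    "simulate_reads",
    "downsample_experiment",
]


@dataclass
class ReadSet:
    """Start positions (bp, 0-based, sorted) of mapped reads on one
    chromosome."""

    chrom: str
    starts: np.ndarray
    read_length: Optional[int] = None

    def __post_init__(self) -> None:
        self.starts = np.sort(np.asarray(self.starts, dtype=np.int64))
        if np.any(self.starts < 0):
            raise ValueError("read start positions must be non-negative")

    @property
    def n_reads(self) -> int:
        return len(self.starts)


@dataclass
class DepthSignal:
    """Non-overlapping tiled window counts over a region."""

    window_bp: int
    window_starts: np.ndarray
    counts: np.ndarray
    chrom: Optional[str] = None

    @property
    def centered(self) -> np.ndarray:
        """Counts minus their global mean (sums to ~0)."""
        return self.counts - self.counts.mean()


def window_counts(
    reads: ReadSet, window_bp: int, region: tuple[int, int]
) -> DepthSignal:
    """Count reads in non-overlapping windows tiling [region_start,
    region_end).  Each read is assigned to exactly one window by its start
    coordinate, so window counts sum to the number of reads in the region.
    """
    if window_bp < 1:
        raise ValueError("window size must be >= 1 bp")
    start, end = region
    if end <= start:
        raise ValueError(f"empty region [{start}, {end})")
    window_starts = np.arange(start, end, window_bp, dtype=np.int64)
    inside = (reads.starts >= start) & (reads.starts < end)
    idx = (reads.starts[inside] - start) // window_bp
    counts = np.bincount(idx, minlength=len(window_starts)).astype(np.float64)
    return DepthSignal(window_bp, window_starts, counts, chrom=reads.chrom)


def center(depth: DepthSignal) -> GCNSignal:
    """Mean-centred window counts as a GCN signal; locations are the window
    start coordinates."""
    if len(depth.counts) < 1:
        raise ValueError("need at least one window")
    return GCNSignal(depth.window_starts, depth.centered, chrom=depth.chrom)


def discrete_amplitude_prior(
    c: float, probs: Optional[Sequence[float]] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude level set {-c, +c, +2c} for clean read-depth data, where c
    is the haploid mean depth per window: a one-copy loss, a one-copy gain
    and a two-copy gain relative to the diploid baseline.  Returns
    (levels, probabilities) suitable for ``Hyperparameters.amplitude_levels``.
    """
    if c <= 0:
        raise ValueError("haploid mean depth c must be positive")
    levels = np.array([-c, c, 2 * c], dtype=np.float64)
    if probs is None:
        probs = np.full(3, 1.0 / 3.0)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != (3,):
        raise ValueError("need one probability per level")
    return levels, probs / probs.sum()


def simulate_reads(
    depth: float,
    region: tuple[int, int],
    read_length: int = 50,
    deletions: Optional[Sequence[tuple[int, int]]] = None,
    het: bool = False,
    chrom: str = "chrS",
    seed: Optional[int] = None,
) -> ReadSet:
    """Synthetic uniformly-mapped reads at a given mean coverage.

    Read starts are uniform over the region; inside each deletion interval
    the rate drops to zero (homozygous) or half (``het=True``).  This is an
    idealised generator: no GC or mappability structure, no paired ends.
    """
    rng = np.random.default_rng(seed)
    start, end = region
    span = end - start
    n_reads = rng.poisson(depth * span / read_length)
    pos = rng.integers(start, end, size=n_reads)
    if deletions:
        keep = np.ones(n_reads, dtype=bool)
        for d_start, d_end in deletions:
            inside = (pos >= d_start) & (pos < d_end)
            if het:
                drop = inside & (rng.random(n_reads) < 0.5)
            else:
                drop = inside
            keep &= ~drop
        pos = pos[keep]
    return ReadSet(chrom, pos, read_length=read_length)


def downsample_experiment(
    reads: ReadSet,
    fractions: Sequence[float],
    window_bp: int = 200,
    region: Optional[tuple[int, int]] = None,
    replicates: int = 3,
    seed: Optional[int] = None,
    hp: Optional[Hyperparameters] = None,
    cfg: Optional[SamplerConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Breakpoint uncertainty versus sequencing depth.

    For each depth fraction and replicate: subsample the reads without
    replacement, rebuild the centred window signal, fit the one-CNV model,
    and record the posterior standard deviations of the start and end
    indices.  The s.d. unit is the window size.  Returns an aggregate table
    (fraction, mean_sd_s, mean_sd_e, detection_rate) and the per-replicate
    detail (including modal s/e and the amplitude summary), where
    "detected" means the 95% credible interval of the amplitude excludes 0.
    """
    hp = hp or Hyperparameters()
    cfg = cfg or SamplerConfig()
    if region is None:
        region = (0, int(reads.starts.max()) + 1)
    fractions = list(fractions)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    seed0 = cfg.resolved_seed() if seed is None else int(seed)
    rng = np.random.default_rng(seed0)
    n_windows = max(1, (region[1] - region[0]) // window_bp)

    rows = []
    for frac in fractions:
        for rep in range(replicates):
            n_keep = max(1, int(round(frac * reads.n_reads)))
            sub_starts = rng.choice(reads.starts, size=n_keep, replace=False)
            if n_keep / n_windows < 1.0:
                warnings.warn(
                    f"fraction {frac} leaves fewer than one read per window "
                    "on average; estimates will be very noisy",
                    stacklevel=2,
                )
            sub = ReadSet(reads.chrom, sub_starts, read_length=reads.read_length)
            signal = center(window_counts(sub, window_bp, region))
            sub_cfg = SamplerConfig(
                n_iter=cfg.n_iter,
                burn_in=cfg.burn_in,
                seed=int(rng.integers(0, 2**31)),
                n_chains=cfg.n_chains,
                blocked=cfg.blocked,
            )
            chain = fit_model(signal, 1, hp, sub_cfg)
            summ = summarize(chain)
            seg = summ.segments[0]
            detected = seg.a_ci[0] > 0 or seg.a_ci[1] < 0
            rows.append(
                {
                    "fraction": frac,
                    "replicate": rep,
                    "n_reads": n_keep,
                    "sd_s": seg.s_sd,
                    "sd_e": seg.e_sd,
                    "s_mode": seg.s_mode,
                    "e_mode": seg.e_mode,
                    "a_mean": seg.a_mean,
                    "a_sd": seg.a_sd,
                    "detected": detected,
                }
            )
    detail = pd.DataFrame(rows)
    agg = (
        detail.groupby("fraction", sort=False)
        .agg(
            mean_sd_s=("sd_s", "mean"),
            mean_sd_e=("sd_e", "mean"),
            detection_rate=("detected", "mean"),
            n_replicates=("replicate", "size"),
        )
        .reset_index()
    )
    return agg, detail
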