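"""Synthetic genomic copy-number data.

Data are generated exactly as the model assumes: a predefined step
function (the true CNV structure) plus iid Gaussian noise, with probe
locations at consecutive integers 1..M.  Named presets reproduce the
standard test configurations: a single-CNV signal (``fig2``), a four-CNV
signal (``fig3``), a widely-separated two-CNV signal (``fig7``), and a
Lai-style benchmark chromosome with one centred CNV parameterised by
probe width and signal-to-noise ratio (``lai_w40_snr1``).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import GCNSignal, ModelState, Segment, step_spectrum

__all__ = [
    "SimulationSpec",
    "simulate_gcn",
    "simulate_lai_style",
    "roc_curve",
    "preset",
    "preset_init",
    "PRESET_NAMES",
]


@dataclass
class SimulationSpec:
    """The generating parameters of a synthetic GCN signal: M probes, the
    true segment/noise state, and the RNG seed.  ``snr`` is an optional
    record of amplitude/noise-sd for convenience; it does not alter the
    generation."""

    M: int
    true_state: ModelState
    seed: Optional[int] = None
    snr: Optional[float] = None

    def __post_init__(self) -> None:
        self.true_state.validate(self.M)


def simulate_gcn(spec: SimulationSpec) -> GCNSignal:
    """x_k = f_k + eps_k with eps_k iid N(0, sigma2); locations 1..M."""
    rng = np.random.default_rng(spec.seed)
    f = step_spectrum(spec.true_state, spec.M)
    noise = rng.normal(0.0, np.sqrt(spec.true_state.sigma2), spec.M)
    return GCNSignal(np.arange(1, spec.M + 1), f + noise)


def _preset_state(name: str) -> tuple[int, ModelState]:
    if name == "fig2":
        return 500, ModelState([Segment(200, 50, 1.5)], 0.4**2)
    if name == "fig3":
        return 1000, ModelState(
            [
                Segment(100, 30, 0.7),
                Segment(200, 20, -0.3),
                Segment(400, 80, 1.5),
                Segment(600, 90, -0.6),
            ],
            0.1**2,
        )
    if name == "fig7":
        return 700, ModelState(
            [Segment(100, 20, 2.0), Segment(600, 20, 2.0)], 0.4**2
        )
    raise KeyError(f"unknown preset {name!r}")


PRESET_NAMES = ("fig2", "fig3", "fig7", "lai_w40_snr1")


def preset(name: str, seed: Optional[int] = None) -> SimulationSpec:
    """A named simulation preset (``lai_w40_snr1`` via
    :func:`simulate_lai_style` for the signal itself)."""
    if name == "lai_w40_snr1":
        state = ModelState([Segment(31, 40, 1.0)], 1.0)
        return SimulationSpec(100, state, seed=seed, snr=1.0)
    M, state = _preset_state(name)
    return SimulationSpec(M, state, seed=seed)


def preset_init(name: str, w_min: int = 2) -> ModelState:
    """The dispersed initial state used for the single-CNV demonstration:
    a segment at s=100 of minimal width with zero amplitude and a small
    initial noise variance."""
    if name != "fig2":
        raise KeyError(f"no initial-state preset for {name!r}")
    return ModelState([Segment(100, max(w_min, 1), 0.0)], 0.1**2)


def simulate_lai_style(
    width_probes: int = 40,
    snr: float = 1.0,
    M: int = 100,
    seed: Optional[int] = None,
) -> tuple[GCNSignal, np.ndarray]:
    """One centred CNV of the given probe width with amplitude snr * sigma
    (sigma = 1), plus a boolean per-probe truth mask for TPR/FPR scoring."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    if width_probes > M:
        raise ValueError("CNV width exceeds the number of probes")
    s = (M - width_probes) // 2 + 1
    state = ModelState([Segment(s, width_probes, snr * 1.0)], 1.0)
    spec = SimulationSpec(M, state, seed=seed, snr=snr)
    truth = np.zeros(M, dtype=bool)
    truth[s - 1 : s - 1 + width_probes] = True
    return simulate_gcn(spec), truth


def roc_curve(
    scores: np.ndarray,
    truth: np.ndarray,
    thresholds: Optional[Sequence[float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe ROC points as the detection threshold on a [0, 1] score
    (e.g. the posterior inclusion frequency) is varied.

    Returns (FPR, TPR) arrays sorted by FPR.  A probe is called at
    threshold t when its score is >= t.  Raises if the truth mask has no
    positive probes.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth mask must have the same shape")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0:
        raise ValueError("truth mask has no positives; TPR is undefined")
    if thresholds is None:
        thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    fpr, tpr = [], []
    for t in thresholds:
        called = scores >= t
        tpr.append(float((called & truth).sum()) / n_pos)
        fpr.append(float((called & ~truth).sum()) / max(n_neg, 1))
    order = np.lexsort((tpr, fpr))
    return np.asarray(fpr)[order], np.asarray(tpr)[order]
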