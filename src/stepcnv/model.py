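"""Core model types and probability functions.

The genomic copy-number (GCN) signal is modelled as a piecewise-constant
"step spectrum": ``N`` non-overlapping segments, each with a start index
``s`` (1-based probe index), a width ``w`` in probes and an amplitude ``a``
in signal units, superimposed on a zero baseline and observed with iid
Gaussian noise of variance ``sigma2``.

Priors: uniform on each segment's start and width (``1/M`` each), a normal
``N(tau, kappa^2)`` on each amplitude (or a finite discrete distribution on
a stated level set for clean read-depth data), and an inverse gamma
``InvGamma(alpha, beta)`` on the noise variance.  Optional informative
windows restrict a segment's start and width to stated intervals, outside
which the prior (and hence the posterior) is zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GCNSignal",
    "Segment",
    "ModelState",
    "Hyperparameters",
    "step_spectrum",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]


@dataclass
class GCNSignal:
    """A sorted genomic copy-number series.

    Parameters
    ----------
    locations
        Integer genomic coordinates (bp) or probe indices, strictly
        increasing, length ``M``.
    values
        Real-valued signal at each location: an array-CGH log2-ratio or a
        mean-centred read count.
    chrom
        Optional chromosome label.
    """

    locations: np.ndarray
    values: np.ndarray
    chrom: Optional[str] = None

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.locations.ndim != 1 or self.values.ndim != 1:
            raise ValueError("locations and values must be 1-D")
        if len(self.locations) != len(self.values):
            raise ValueError("locations and values must have equal length")
        if len(self.locations) < 1:
            raise ValueError("signal must contain at least one point (M >= 1)")
        if np.any(np.diff(self.locations) <= 0):
            raise ValueError("locations must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")

    @property
    def M(self) -> int:
        return len(self.values)


@dataclass
class Segment:
    """One CNV: start probe index ``s`` (1-based), width ``w`` >= 1 probes,
    amplitude ``a`` in signal units.  The inclusive end is ``e = s + w - 1``."""

    s: int
    w: int
    a: float

    def __post_init__(self) -> None:
        self.s = int(self.s)
        self.w = int(self.w)
        self.a = float(self.a)
        if self.s < 1:
            raise ValueError(f"segment start must be >= 1, got {self.s}")
        if self.w < 1:
            raise ValueError(f"segment width must be >= 1, got {self.w}")

    @property
    def e(self) -> int:
        """Inclusive 1-based end index."""
        return self.s + self.w - 1


@dataclass
class ModelState:
    """Fixed-N parameter state: segments sorted by start, plus noise variance."""

    segments: list[Segment] = field(default_factory=list)
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda seg: seg.s)
        self.sigma2 = float(self.sigma2)

    @property
    def n(self) -> int:
        return len(self.segments)

    def copy(self) -> "ModelState":
        return ModelState(
            [Segment(seg.s, seg.w, seg.a) for seg in self.segments], self.sigma2
        )

    def overlaps(self) -> bool:
        """True if any two segments share a probe index."""
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.s <= prev.e:
                return True
        return False

    def validate(self, M: int) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        for seg in self.segments:
            if seg.e > M:
                raise ValueError(
                    f"segment ({seg.s}, {seg.w}) extends past the last probe (M={M})"
                )
        if self.overlaps():
            raise ValueError("segments must be pairwise non-overlapping")


@dataclass
class Hyperparameters:
    """Prior settings.

    ``tau``/``kappa`` are the amplitude prior mean and standard deviation,
    ``alpha``/``beta`` the inverse-gamma shape and scale of the noise
    variance.  The defaults (0, 100, 1, 1) make both priors effectively
    non-informative at array-CGH signal scales.

    ``w_min``/``w_max`` bound the discrete scan over candidate widths in the
    sampler; ``w_max=None`` means ``min(M, 500)``.  ``informative_windows``
    optionally gives, per segment, an ``(s_lo, s_hi, w_lo, w_hi)`` support
    restriction (1-based, inclusive); ``None`` entries leave a segment
    unrestricted.  ``amplitude_levels`` replaces the normal amplitude prior
    by a finite ``(levels, probabilities)`` support, as appropriate for
    clean read-depth data where amplitudes aggregate at multiples of the
    haploid depth.
    """

    tau: float = 0.0
    kappa: float = 100.0
    alpha: float = 1.0
    beta: float = 1.0
    n_max: int = 5
    w_min: int = 2
    w_max: Optional[int] = None
    informative_windows: Optional[Sequence[Optional[tuple[int, int, int, int]]]] = None
    amplitude_levels: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.w_min < 1:
            raise ValueError("w_min must be >= 1")
        if self.w_max is not None and self.w_max < self.w_min:
            raise ValueError("w_max must be >= w_min")
        if self.amplitude_levels is not None:
            levels, probs = self.amplitude_levels
            levels = np.asarray(levels, dtype=np.float64)
            probs = np.asarray(probs, dtype=np.float64)
            if levels.shape != probs.shape or levels.ndim != 1:
                raise ValueError("amplitude levels and probabilities must match")
            if np.any(probs <= 0) or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
                raise ValueError("amplitude level probabilities must sum to 1")
            self.amplitude_levels = (levels, probs)

    def effective_w_max(self, M: int) -> int:
        cap = 500 if self.w_max is None else self.w_max
        return max(self.w_min, min(cap, M))

    def window_for(self, j: int) -> Optional[tuple[int, int, int, int]]:
        """Informative (s_lo, s_hi, w_lo, w_hi) window for segment ``j`` (0-based)."""
        if self.informative_windows is None:
            return None
        if j >= len(self.informative_windows):
            return None
        return self.informative_windows[j]


def step_spectrum(state: ModelState, M: int) -> np.ndarray:
    """Evaluate the noiseless step spectrum f_k, k = 1..M.

    f_k equals the amplitude of the segment covering probe k and 0 outside
    all segments.  Raises if any segment falls outside ``[1, M]``.
    """
    f = np.zeros(int(M), dtype=np.float64)
    for seg in state.segments:
        if seg.e > M:
            raise ValueError(
                f"segment ({seg.s}, {seg.w}) out of range for M={M}"
            )
        f[seg.s - 1 : seg.e] = seg.a
    return f


def log_likelihood(data: GCNSignal, state: ModelState) -> float:
    """Gaussian log-likelihood of the data under a state.

    ``-psi^2/2 - (M/2) ln(2 pi sigma^2)`` with
    ``psi^2 = sum_k (x_k - f_k)^2 / sigma^2``.
    """
    if state.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    f = step_spectrum(state, data.M)
    psi2 = float(np.sum((data.values - f) ** 2)) / state.sigma2
    return -0.5 * psi2 - 0.5 * data.M * math.log(2.0 * math.pi * state.sigma2)


def _log_amplitude_prior(a: float, j: int, hp: Hyperparameters) -> float:
    if hp.amplitude_levels is not None:
        levels, probs = hp.amplitude_levels
        hit = np.isclose(levels, a, rtol=1e-12, atol=1e-12)
        if not np.any(hit):
            return -math.inf
        return float(np.log(probs[np.argmax(hit)]))
    return float(stats.norm.logpdf(a, loc=hp.tau, scale=hp.kappa))


def log_prior(state: ModelState, hp: Hyperparameters, M: int) -> float:
    """Log prior density of a state (the constant 1/N_max term is dropped).

    Per segment: ``-2 ln M`` for the uniform start and width factors (or the
    log mass of the informative windows when set, with ``-inf`` outside
    their support), plus the amplitude log-density.  Plus the inverse-gamma
    log-density of ``sigma2``.  States violating an informative window are
    out of support and return ``-inf`` rather than raising.
    """
    lp = 0.0
    for j, seg in enumerate(state.segments):
        window = hp.window_for(j)
        if window is None:
            lp += -2.0 * math.log(M)
        else:
            s_lo, s_hi, w_lo, w_hi = window
            if not (s_lo <= seg.s <= s_hi and w_lo <= seg.w <= w_hi):
                return -math.inf
            lp += -math.log(s_hi - s_lo + 1) - math.log(w_hi - w_lo + 1)
        amp = _log_amplitude_prior(seg.a, j, hp)
        if amp == -math.inf:
            return -math.inf
        lp += amp
    lp += float(stats.invgamma.logpdf(state.sigma2, hp.alpha, scale=hp.beta))
    return lp


def log_posterior(data: GCNSignal, state: ModelState, hp: Hyperparameters) -> float:
    """Unnormalised log posterior: log-likelihood plus log-prior."""
    lp = log_prior(state, hp, data.M)
    if lp == -math.inf:
        return -math.inf
    return log_likelihood(data, state) + lp
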