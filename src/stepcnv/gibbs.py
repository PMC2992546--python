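"""Gibbs sampler for the stepwise CNV model at fixed segment count N.

Each sweep updates every segment and then the noise variance:

* ``(s_j, w_j)`` is drawn from a discrete conditional evaluated over all
  candidate (start, width) pairs with ``s in [1, M]`` and
  ``w in [w_min, w_max]`` that do not overlap the other segments and lie
  inside any informative window.  Two variants are provided: the
  fixed-amplitude full conditional (``sample_position_width``), and a
  blocked update that integrates the amplitude out of the scan under its
  conjugate prior and then redraws it (``blocked=True``, the default) —
  the blocked move samples ``(s_j, w_j, a_j)`` as one block and mixes
  across well-separated modes that trap the fixed-amplitude scan.
* ``a_j`` is drawn from its conjugate normal conditional (or from the
  discrete conditional when a finite amplitude level set is configured).
* ``sigma2`` is drawn from its conjugate inverse-gamma conditional with
  shape ``alpha + M/2`` and scale ``beta + RSS/2``, where RSS is the
  residual sum of squares about the current fitted spectrum.

The per-candidate scan cost is O(1) via prefix sums of the residual signal,
so a sweep is O(M * W) for W candidate widths.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Optional

import numpy as np

from .model import (
    GCNSignal,
    Hyperparameters,
    ModelState,
    Segment,
    log_likelihood,
    log_prior,
    log_posterior,
    step_spectrum,
)

__all__ = [
    "SamplerConfig",
    "Chain",
    "PosteriorSummary",
    "SegmentSummary",
    "ConfigurationError",
    "position_width_conditional",
    "sample_position_width",
    "amplitude_conditional",
    "sample_amplitude",
    "sigma2_conditional",
    "sample_sigma2",
    "run_gibbs",
    "fit_model",
    "summarize",
    "inclusion_frequency",
]


class ConfigurationError(RuntimeError):
    """Raised when sampler constraints leave no admissible candidate state."""


@dataclass
class SamplerConfig:
    """MCMC run settings.

    ``n_iter`` total sweeps (default 500), of which the first ``burn_in``
    (default 100) are discarded by summaries and evidence estimation.
    ``n_chains`` independent chains are run from dispersed random initial
    states by :func:`fit_model`; the chain with the highest mean
    post-burn-in log posterior is kept.  ``blocked`` selects the blocked
    (amplitude-collapsed) segment move.  ``init`` optionally fixes the
    initial state of every chain.
    """

    n_iter: int = 500
    burn_in: int = 100
    seed: Optional[int] = None
    n_chains: int = 2
    init: Optional[ModelState] = None
    blocked: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    def resolved_seed(self) -> int:
        if self.seed is None:
            return int(np.random.SeedSequence().entropy % (2**31))
        return int(self.seed)


@dataclass
class Chain:
    """A stored Gibbs chain: per-iteration segment parameters (sorted by
    start), noise variance, data log-likelihood and unnormalised log
    posterior."""

    s: np.ndarray          # (T, N) int
    w: np.ndarray          # (T, N) int
    a: np.ndarray          # (T, N) float
    sigma2: np.ndarray     # (T,)
    loglik: np.ndarray     # (T,)
    logpost: np.ndarray    # (T,)
    burn_in: int
    seed: int
    M: int

    @property
    def n(self) -> int:
        return self.s.shape[1]

    @property
    def n_iter(self) -> int:
        return self.s.shape[0]

    def state_at(self, t: int) -> ModelState:
        segs = [
            Segment(int(self.s[t, j]), int(self.w[t, j]), float(self.a[t, j]))
            for j in range(self.n)
        ]
        return ModelState(segs, float(self.sigma2[t]))

    def states(self) -> Iterator[ModelState]:
        for t in range(self.n_iter):
            yield self.state_at(t)

    def post_burn(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.burn_in :]

    @property
    def loglik_post(self) -> np.ndarray:
        return self.loglik[self.burn_in :]

    def to_frame(self):
        """Trace as a tidy DataFrame (one row per iteration)."""
        import pandas as pd

        cols = {"iteration": np.arange(self.n_iter)}
        for j in range(self.n):
            cols[f"s{j + 1}"] = self.s[:, j]
            cols[f"w{j + 1}"] = self.w[:, j]
            cols[f"a{j + 1}"] = self.a[:, j]
        cols["sigma2"] = self.sigma2
        cols["loglik"] = self.loglik
        cols["logpost"] = self.logpost
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# candidate-scan machinery


@lru_cache(maxsize=16)
def _candidate_grid(M: int, w_min: int, w_max: int):
    """Flat arrays (s0, w, e0, wi, widths) of all in-range candidates; s0 is
    the 0-based start, e0 the exclusive end, wi the index of each
    candidate's width in ``widths`` (for gathering per-width terms).
    Cached per (M, w_min, w_max)."""
    widths = np.arange(w_min, w_max + 1, dtype=np.int64)
    s0 = np.repeat(np.arange(M, dtype=np.int64), len(widths))
    w = np.tile(widths, M)
    wi = np.tile(np.arange(len(widths)), M)
    e0 = s0 + w
    keep = e0 <= M
    return s0[keep], w[keep], e0[keep], wi[keep], widths


def _occupancy_prefix(state: ModelState, skip: int, M: int) -> np.ndarray:
    """Prefix sums of the probe-occupancy indicator of all segments except
    ``skip``; occ[e0]-occ[s0] > 0 iff [s0, e0) touches another segment."""
    occ = np.zeros(M + 1, dtype=np.int64)
    ind = np.zeros(M, dtype=np.int64)
    for k, seg in enumerate(state.segments):
        if k == skip:
            continue
        ind[seg.s - 1 : seg.e] = 1
    np.cumsum(ind, out=occ[1:])
    return occ


def _residual_without(data: GCNSignal, state: ModelState, skip: int) -> np.ndarray:
    resid = data.values.copy()
    for k, seg in enumerate(state.segments):
        if k == skip:
            continue
        resid[seg.s - 1 : seg.e] -= seg.a
    return resid


def _masked_candidates(
    state: ModelState,
    j: int,
    M: int,
    hp: Hyperparameters,
):
    """Flat candidate arrays (s0, w, e0, wi, widths) restricted to pairs
    that avoid the other segments and honour segment j's informative
    window.  Returns the unrestricted grid when no constraint applies."""
    s0, w, e0, wi, widths = _candidate_grid(M, hp.w_min, hp.effective_w_max(M))
    window = hp.window_for(j)
    if state.n <= 1 and window is None:
        return s0, w, e0, wi, widths
    valid = np.ones(len(s0), dtype=bool)
    if state.n > 1:
        occ = _occupancy_prefix(state, j, M)
        valid &= (occ[e0] - occ[s0]) == 0
    if window is not None:
        s_lo, s_hi, w_lo, w_hi = window
        valid &= (s0 + 1 >= s_lo) & (s0 + 1 <= s_hi) & (w >= w_lo) & (w <= w_hi)
    if not np.any(valid):
        raise ConfigurationError(
            f"no admissible (s, w) candidate for segment {j + 1}: the "
            "informative window conflicts with the other segments or bounds"
        )
    return s0[valid], w[valid], e0[valid], wi[valid], widths


def _window_sums(resid: np.ndarray, s0: np.ndarray, e0: np.ndarray) -> np.ndarray:
    prefix = np.concatenate(([0.0], np.cumsum(resid)))
    return prefix[e0] - prefix[s0]


def _draw_categorical(logw: np.ndarray, rng: np.random.Generator) -> int:
    p = np.exp(logw - logw.max())
    cdf = np.cumsum(p)
    u = rng.random() * cdf[-1]
    return min(int(np.searchsorted(cdf, u, side="right")), len(cdf) - 1)


def position_width_conditional(
    j: int, state: ModelState, data: GCNSignal, hp: Hyperparameters
):
    """The discrete full conditional of (s_j, w_j) at the current a_j, sigma2.

    Returns ``(candidates, logprobs)``: an (K, 2) integer array of (s, w)
    pairs and their normalised log probabilities.
    """
    M = data.M
    s0, w, e0, _, _ = _masked_candidates(state, j, M, hp)
    resid = _residual_without(data, state, j)
    S = _window_sums(resid, s0, e0)
    a = state.segments[j].a
    logw = (2.0 * a * S - a * a * w) / (2.0 * state.sigma2)
    logw = logw - _logsumexp(logw)
    cands = np.stack([s0 + 1, w], axis=1)
    return cands, logw


def _logsumexp(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + math.log(float(np.sum(np.exp(x - m))))


def sample_position_width(
    j: int,
    state: ModelState,
    data: GCNSignal,
    hp: Hyperparameters,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw (s_j, w_j) from its full conditional at the current amplitude."""
    cands, logp = position_width_conditional(j, state, data, hp)
    k = _draw_categorical(logp, rng)
    return int(cands[k, 0]), int(cands[k, 1])


def _collapsed_logweights(
    j: int, state: ModelState, data: GCNSignal, hp: Hyperparameters
):
    """Log weights of (s_j, w_j) with a_j integrated out of the likelihood
    under its prior (normal conjugate case) or summed over the finite level
    set (discrete case).  Constant terms are dropped."""
    M = data.M
    s0, w, e0, wi, widths = _masked_candidates(state, j, M, hp)
    resid = _residual_without(data, state, j)
    S = _window_sums(resid, s0, e0)
    sigma2 = state.sigma2
    if hp.amplitude_levels is not None:
        levels, probs = hp.amplitude_levels
        # logsumexp over levels of  log p_l + (2 l S - l^2 w) / (2 sigma^2)
        terms = (
            np.log(probs)[None, :]
            + (2.0 * levels[None, :] * S[:, None] - (levels**2)[None, :] * w[:, None])
            / (2.0 * sigma2)
        )
        m = terms.max(axis=1)
        logw = m + np.log(np.exp(terms - m[:, None]).sum(axis=1))
    else:
        # per-width terms of the collapsed weight, gathered per candidate
        P = 1.0 / (hp.kappa * hp.kappa)
        A_w = widths / sigma2
        const_w = 0.5 * (math.log(P) - np.log(P + A_w))
        quad_w = 1.0 / (2.0 * (P + A_w))
        B = S / sigma2 + P * hp.tau
        logw = const_w[wi] + B * B * quad_w[wi]
    return s0 + 1, w, logw


def _sample_sw_blocked(
    j: int,
    state: ModelState,
    data: GCNSignal,
    hp: Hyperparameters,
    rng: np.random.Generator,
) -> tuple[int, int]:
    s, w, logw = _collapsed_logweights(j, state, data, hp)
    k = _draw_categorical(logw, rng)
    return int(s[k]), int(w[k])


def amplitude_conditional(
    j: int, state: ModelState, data: GCNSignal, hp: Hyperparameters
) -> tuple[float, float]:
    """Mean and variance of the conjugate normal conditional of a_j:

    mean = [(1/kappa^2) tau + (w/sigma^2) xbar] / (1/kappa^2 + w/sigma^2),
    var  = 1 / (1/kappa^2 + w/sigma^2),

    with xbar the mean residual signal inside segment j (other segments
    subtracted).
    """
    seg = state.segments[j]
    resid = _residual_without(data, state, j)
    xbar = float(np.mean(resid[seg.s - 1 : seg.e]))
    prior_prec = 1.0 / (hp.kappa * hp.kappa)
    lik_prec = seg.w / state.sigma2
    prec = prior_prec + lik_prec
    mean = (prior_prec * hp.tau + lik_prec * xbar) / prec
    return mean, 1.0 / prec


def sample_amplitude(
    j: int,
    state: ModelState,
    data: GCNSignal,
    hp: Hyperparameters,
    rng: np.random.Generator,
) -> float:
    """Draw a_j from its conditional: conjugate normal, or the discrete
    conditional over the configured amplitude levels."""
    if hp.amplitude_levels is not None:
        levels, probs = hp.amplitude_levels
        seg = state.segments[j]
        resid = _residual_without(data, state, j)
        S = float(np.sum(resid[seg.s - 1 : seg.e]))
        logw = np.log(probs) + (2.0 * levels * S - levels**2 * seg.w) / (
            2.0 * state.sigma2
        )
        return float(levels[_draw_categorical(logw, rng)])
    mean, var = amplitude_conditional(j, state, data, hp)
    return float(rng.normal(mean, math.sqrt(var)))


def sigma2_conditional(rss: float, M: int, hp: Hyperparameters) -> tuple[float, float]:
    """Shape and scale of the inverse-gamma conditional of sigma2:
    ``InvGamma(alpha + M/2, beta + RSS/2)`` with RSS the residual sum of
    squares about the fitted spectrum."""
    return hp.alpha + M / 2.0, hp.beta + rss / 2.0


def sample_sigma2(
    state: ModelState,
    data: GCNSignal,
    hp: Hyperparameters,
    rng: np.random.Generator,
) -> float:
    f = step_spectrum(state, data.M)
    rss = float(np.sum((data.values - f) ** 2))
    shape, scale = sigma2_conditional(rss, data.M, hp)
    return scale / float(rng.gamma(shape))


# ---------------------------------------------------------------------------
# chain driver


def _first_free_slot(state: ModelState, M: int, w: int) -> int:
    """Smallest 1-based start where a width-w segment fits without overlap."""
    occupied = np.zeros(M, dtype=bool)
    for seg in state.segments:
        occupied[seg.s - 1 : seg.e] = True
    run = 0
    for i in range(M):
        run = 0 if occupied[i] else run + 1
        if run == w:
            return i - w + 2
    raise ConfigurationError(f"no room for a width-{w} segment in M={M}")


def _activate_segment(
    state: ModelState,
    j: int,
    data: GCNSignal,
    hp: Hyperparameters,
    rng: np.random.Generator,
    blocked: bool,
) -> None:
    """Introduce segment j (zero amplitude, placed at the first free slot)
    and immediately resample it.  Activating segments one at a time during
    the first sweep is a sequential matching-pursuit start: each new
    segment scans the residuals left by the previous ones, so the most
    prominent CNV is picked up first and no fledgling segment blocks a
    larger one."""
    window = hp.window_for(j)
    if window is not None:
        s_lo, _, w_lo, w_hi = window
        w0 = int(np.clip(hp.w_min, w_lo, w_hi))
        state.segments.append(Segment(s_lo, w0, 0.0))
    else:
        w0 = hp.w_min
        state.segments.append(Segment(_first_free_slot(state, data.M, w0), w0, 0.0))
    if blocked:
        s, w = _sample_sw_blocked(j, state, data, hp, rng)
    else:
        s, w = sample_position_width(j, state, data, hp, rng)
    seg = state.segments[j]
    seg.s, seg.w = s, w
    seg.a = sample_amplitude(j, state, data, hp, rng)


def run_gibbs(
    data: GCNSignal,
    n: int,
    hp: Optional[Hyperparameters] = None,
    cfg: Optional[SamplerConfig] = None,
) -> Chain:
    """Run one Gibbs chain for the fixed-N model and record every sweep.

    For ``n == 0`` only sigma2 is sampled (its draws are then iid from the
    conjugate posterior).  Segments are re-sorted by start after each sweep
    so labels are canonical; the recorded log-likelihood feeds evidence
    estimation downstream.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    hp = hp or Hyperparameters()
    cfg = cfg or SamplerConfig()
    seed = cfg.resolved_seed()
    rng = np.random.default_rng(seed)
    M = data.M

    if cfg.init is not None:
        state = cfg.init.copy()
        if state.n != n:
            raise ValueError("initial state has wrong number of segments")
        state.validate(M)
    else:
        var = float(np.var(data.values))
        state = ModelState([], var if var > 0 else 1.0)

    T = cfg.n_iter
    s_arr = np.zeros((T, n), dtype=np.int64)
    w_arr = np.zeros((T, n), dtype=np.int64)
    a_arr = np.zeros((T, n), dtype=np.float64)
    sig_arr = np.zeros(T, dtype=np.float64)
    ll_arr = np.zeros(T, dtype=np.float64)
    lp_arr = np.zeros(T, dtype=np.float64)

    for t in range(T):
        for j in range(n):
            if j >= state.n:  # sequential activation during the first sweep
                _activate_segment(state, j, data, hp, rng, cfg.blocked)
                continue
            if cfg.blocked:
                s, w = _sample_sw_blocked(j, state, data, hp, rng)
            else:
                s, w = sample_position_width(j, state, data, hp, rng)
            seg = state.segments[j]
            seg.s, seg.w = s, w
            seg.a = sample_amplitude(j, state, data, hp, rng)
        state.sigma2 = sample_sigma2(state, data, hp, rng)
        if hp.informative_windows is None:
            # canonical labels; skipped when windows tie priors to labels
            state.segments.sort(key=lambda seg: seg.s)
        for j, seg in enumerate(state.segments):
            s_arr[t, j], w_arr[t, j], a_arr[t, j] = seg.s, seg.w, seg.a
        sig_arr[t] = state.sigma2
        ll_arr[t] = log_likelihood(data, state)
        lp_arr[t] = ll_arr[t] + log_prior(state, hp, M)

    return Chain(
        s=s_arr,
        w=w_arr,
        a=a_arr,
        sigma2=sig_arr,
        loglik=ll_arr,
        logpost=lp_arr,
        burn_in=cfg.burn_in,
        seed=seed,
        M=M,
    )


def fit_model(
    data: GCNSignal,
    n: int,
    hp: Optional[Hyperparameters] = None,
    cfg: Optional[SamplerConfig] = None,
) -> Chain:
    """Fit the fixed-N model: run ``cfg.n_chains`` chains from dispersed
    random starts and return the one with the highest mean post-burn-in log
    posterior (the chains that found the dominant mode)."""
    cfg = cfg or SamplerConfig()
    seed = cfg.resolved_seed()
    children = np.random.SeedSequence(seed).spawn(cfg.n_chains)
    best: Optional[Chain] = None
    best_score = -math.inf
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        sub = SamplerConfig(
            n_iter=cfg.n_iter,
            burn_in=cfg.burn_in,
            seed=child_seed,
            n_chains=1,
            init=cfg.init,
            blocked=cfg.blocked,
        )
        chain = run_gibbs(data, n, hp, sub)
        score = float(np.mean(chain.post_burn(chain.logpost)))
        if score > best_score:
            best, best_score = chain, score
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# chain summaries


@dataclass
class SegmentSummary:
    s_mode: int
    s_sd: float
    s_ci: tuple[float, float]
    w_mode: int
    w_sd: float
    e_mode: int
    e_sd: float
    e_ci: tuple[float, float]
    a_mean: float
    a_sd: float
    a_ci: tuple[float, float]


@dataclass
class PosteriorSummary:
    """Point estimates, posterior standard deviations and 95% credible
    intervals (mean +/- 1.96 sd) from the post-burn-in draws.  Discrete
    parameters (s, w, e) are summarised by their posterior mode, continuous
    ones (a, sigma) by the posterior mean."""

    n: int
    n_draws: int
    seed: int
    segments: list[SegmentSummary] = field(default_factory=list)
    sigma_mean: float = 0.0
    sigma_sd: float = 0.0
    sigma_ci: tuple[float, float] = (0.0, 0.0)


def _mode(arr: np.ndarray) -> int:
    values, counts = np.unique(arr, return_counts=True)
    return int(values[np.argmax(counts)])  # ties break toward the smaller value


def _sd(arr: np.ndarray) -> float:
    return float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0


def _ci(mean: float, sd: float) -> tuple[float, float]:
    return (mean - 1.96 * sd, mean + 1.96 * sd)


def summarize(chain: Chain, burn_in: Optional[int] = None) -> PosteriorSummary:
    """Summarise a chain after dropping the burn-in draws."""
    b = chain.burn_in if burn_in is None else burn_in
    if b >= chain.n_iter:
        raise ValueError("burn-in leaves no draws to summarise")
    out = PosteriorSummary(n=chain.n, n_draws=chain.n_iter - b, seed=chain.seed)
    sigma = np.sqrt(chain.sigma2[b:])
    out.sigma_mean = float(np.mean(sigma))
    out.sigma_sd = _sd(sigma)
    out.sigma_ci = _ci(out.sigma_mean, out.sigma_sd)
    for j in range(chain.n):
        s = chain.s[b:, j]
        w = chain.w[b:, j]
        e = s + w - 1
        a = chain.a[b:, j]
        a_mean, a_sd = float(np.mean(a)), _sd(a)
        out.segments.append(
            SegmentSummary(
                s_mode=_mode(s),
                s_sd=_sd(s),
                s_ci=_ci(float(np.mean(s)), _sd(s)),
                w_mode=_mode(w),
                w_sd=_sd(w),
                e_mode=_mode(e),
                e_sd=_sd(e),
                e_ci=_ci(float(np.mean(e)), _sd(e)),
                a_mean=a_mean,
                a_sd=a_sd,
                a_ci=_ci(a_mean, a_sd),
            )
        )
    return out


def inclusion_frequency(chain: Chain, burn_in: Optional[int] = None) -> np.ndarray:
    """Per-probe fraction of post-burn-in draws in which the probe lies
    inside any segment — a per-probe CNV detection score in [0, 1]."""
    b = chain.burn_in if burn_in is None else burn_in
    counts = np.zeros(chain.M, dtype=np.float64)
    T = chain.n_iter
    for t in range(b, T):
        for j in range(chain.n):
            s = chain.s[t, j]
            counts[s - 1 : s - 1 + chain.w[t, j]] += 1.0
    return counts / max(T - b, 1)
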