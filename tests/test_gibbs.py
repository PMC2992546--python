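"""Gibbs sampler: conjugate conditionals against hand formulas, the
discrete (s, w) scan against brute-force enumeration, chain mechanics and
posterior summaries."""
import math

import numpy as np
import pytest

from stepcnv.gibbs import (
    Chain,
    ConfigurationError,
    SamplerConfig,
    _collapsed_logweights,
    amplitude_conditional,
    fit_model,
    inclusion_frequency,
    position_width_conditional,
    run_gibbs,
    sample_amplitude,
    sample_position_width,
    sample_sigma2,
    sigma2_conditional,
    summarize,
)
from stepcnv.model import (
    GCNSignal,
    Hyperparameters,
    ModelState,
    Segment,
    log_posterior,
    step_spectrum,
)
from stepcnv.simulate import preset, simulate_gcn


class TestAmplitudeConditional:
    def test_moments_match_conjugate_formula(self):
        # window of 50 probes with residual mean exactly 1.5
        M = 100
        values = np.zeros(M)
        values[9:59] = 1.5
        data = GCNSignal(np.arange(1, M + 1), values)
        state = ModelState([Segment(10, 50, 0.0)], 0.16)
        hp = Hyperparameters(tau=0.0, kappa=100.0)
        mean, var = amplitude_conditional(0, state, data, hp)
        prior_prec = 1.0 / 100.0**2
        lik_prec = 50 / 0.16
        assert var == pytest.approx(1.0 / (prior_prec + lik_prec), abs=1e-12)
        assert mean == pytest.approx(
            (lik_prec / (prior_prec + lik_prec)) * 1.5, abs=1e-9
        )
        assert var == pytest.approx(3.19999968e-3, abs=1e-9)

    def test_flat_prior_limit(self):
        M = 20
        values = np.full(M, 0.8)
        data = GCNSignal(np.arange(1, M + 1), values)
        state = ModelState([Segment(5, 10, 0.0)], 0.25)
        hp = Hyperparameters(kappa=1e9)
        mean, var = amplitude_conditional(0, state, data, hp)
        assert mean == pytest.approx(0.8, rel=1e-9)
        assert var == pytest.approx(0.25 / 10, rel=1e-6)

    def test_discrete_levels_sample_from_support(self, rng):
        levels = (np.array([-2.0, 2.0, 4.0]), np.full(3, 1 / 3))
        hp = Hyperparameters(amplitude_levels=levels)
        values = np.zeros(30)
        values[4:14] = 2.1
        data = GCNSignal(np.arange(1, 31), values)
        state = ModelState([Segment(5, 10, 2.0)], 0.2)
        draws = {sample_amplitude(0, state, data, hp, rng) for _ in range(50)}
        assert draws <= {-2.0, 2.0, 4.0}
        assert 2.0 in draws  # the level matching the data dominates


class TestSigma2Conditional:
    def test_shape_scale_formula(self):
        shape, scale = sigma2_conditional(80.0, 500, Hyperparameters(alpha=1, beta=1))
        assert (shape, scale) == (251.0, 41.0)
        assert scale / (shape - 1) == pytest.approx(0.164, abs=1e-12)

    def test_no_data_limit_recovers_prior(self):
        shape, scale = sigma2_conditional(0.0, 0, Hyperparameters(alpha=1, beta=1))
        assert (shape, scale) == (1.0, 1.0)

    def test_sampled_mean_matches_analytic(self, rng):
        state = ModelState([Segment(3, 4, 1.0)], 0.5)
        data = GCNSignal(np.arange(1, 11), step_spectrum(state, 10) + 0.3)
        hp = Hyperparameters(alpha=2.0, beta=1.5)
        rss = 10 * 0.3**2
        shape, scale = sigma2_conditional(rss, 10, hp)
        analytic_mean = scale / (shape - 1)
        draws = np.array([sample_sigma2(state, data, hp, rng) for _ in range(20000)])
        analytic_sd = math.sqrt(scale**2 / ((shape - 1) ** 2 * (shape - 2)))
        se = analytic_sd / math.sqrt(len(draws))
        assert abs(draws.mean() - analytic_mean) < 4 * se


def enumerate_conditional(j, state, data, hp):
    """Brute-force oracle: evaluate the full log posterior at every
    candidate (s, w) for segment j, holding everything else fixed."""
    M = data.M
    others = [seg for k, seg in enumerate(state.segments) if k != j]
    occupied = np.zeros(M, dtype=bool)
    for seg in others:
        occupied[seg.s - 1 : seg.e] = True
    cands, logps = [], []
    for s in range(1, M + 1):
        for w in range(hp.w_min, hp.effective_w_max(M) + 1):
            if s + w - 1 > M or occupied[s - 1 : s + w - 1].any():
                continue
            window = hp.window_for(j)
            if window is not None:
                s_lo, s_hi, w_lo, w_hi = window
                if not (s_lo <= s <= s_hi and w_lo <= w <= w_hi):
                    continue
            trial = [Segment(seg.s, seg.w, seg.a) for seg in others]
            trial.insert(0, Segment(s, w, state.segments[j].a))
            lp = log_posterior(data, ModelState(trial, state.sigma2), hp)
            cands.append((s, w))
            logps.append(lp)
    logps = np.array(logps)
    probs = np.exp(logps - logps.max())
    return cands, probs / probs.sum()


class TestPositionWidthScan:
    def test_matches_enumeration_oracle(self, toy_signal):
        hp = Hyperparameters(w_min=1, w_max=5)
        state = ModelState([Segment(3, 3, 1.5)], 0.09)
        cands, logp = position_width_conditional(0, state, toy_signal, hp)
        oracle_cands, oracle_p = enumerate_conditional(0, state, toy_signal, hp)
        assert [tuple(c) for c in cands] == oracle_cands
        np.testing.assert_allclose(np.exp(logp), oracle_p, rtol=1e-9, atol=1e-12)

    def test_oracle_agreement_with_second_segment(self, toy_signal):
        hp = Hyperparameters(w_min=1, w_max=3)
        state = ModelState([Segment(3, 3, 1.5), Segment(7, 2, -0.5)], 0.09)
        cands, logp = position_width_conditional(0, state, toy_signal, hp)
        oracle_cands, oracle_p = enumerate_conditional(0, state, toy_signal, hp)
        assert [tuple(c) for c in cands] == oracle_cands
        np.testing.assert_allclose(np.exp(logp), oracle_p, rtol=1e-9, atol=1e-12)

    def test_noise_free_step_is_point_mass(self, rng):
        state = ModelState([Segment(4, 3, 2.0)], 1.0)
        data = GCNSignal(np.arange(1, 13), step_spectrum(state, 12))
        scan_state = ModelState([Segment(4, 3, 2.0)], 1e-6)
        hp = Hyperparameters(w_min=1, w_max=6)
        cands, logp = position_width_conditional(0, scan_state, data, hp)
        k = int(np.argmax(logp))
        assert tuple(cands[k]) == (4, 3)
        assert math.exp(logp[k]) > 1 - 1e-9
        assert sample_position_width(0, scan_state, data, hp, rng) == (4, 3)

    def test_empty_candidate_set_raises(self, rng):
        # the informative window for segment 1 is fully occupied by segment 2
        hp = Hyperparameters(w_min=2, w_max=3, informative_windows=[(4, 5, 2, 3)])
        data = GCNSignal(np.arange(1, 11), np.zeros(10))
        state = ModelState([Segment(1, 2, 0.0), Segment(3, 6, 1.0)], 1.0)
        with pytest.raises(ConfigurationError):
            sample_position_width(0, state, data, hp, rng)

    def test_blocked_weights_match_numeric_amplitude_integral(self, toy_signal):
        """The amplitude-collapsed scan weights equal the brute-force
        numerical integral of likelihood x amplitude prior per candidate."""
        hp = Hyperparameters(w_min=1, w_max=4, kappa=2.0, tau=0.3)
        state = ModelState([Segment(3, 3, 1.5)], 0.09)
        s, w, logw = _collapsed_logweights(0, state, toy_signal, hp)
        probs = np.exp(logw - logw.max())
        probs /= probs.sum()
        a_grid = np.linspace(-12, 12, 4001)
        oracle = []
        for sk, wk in zip(s, w):
            vals = [
                log_posterior(
                    toy_signal, ModelState([Segment(sk, wk, a)], 0.09), hp
                )
                for a in a_grid
            ]
            vals = np.array(vals)
            m = vals.max()
            oracle.append(m + math.log(np.trapezoid(np.exp(vals - m), a_grid)))
        oracle = np.array(oracle)
        op = np.exp(oracle - oracle.max())
        op /= op.sum()
        np.testing.assert_allclose(probs, op, rtol=5e-6, atol=1e-10)


class TestRunGibbs:
    def test_reproducible_given_seed(self, toy_signal):
        cfg = SamplerConfig(n_iter=50, burn_in=10, seed=123, n_chains=1)
        c1 = run_gibbs(toy_signal, 1, None, cfg)
        c2 = run_gibbs(toy_signal, 1, None, cfg)
        np.testing.assert_array_equal(c1.s, c2.s)
        np.testing.assert_array_equal(c1.a, c2.a)
        np.testing.assert_array_equal(c1.sigma2, c2.sigma2)
        c3 = run_gibbs(toy_signal, 1, None, SamplerConfig(n_iter=50, burn_in=10, seed=124, n_chains=1))
        assert not np.array_equal(c1.sigma2, c3.sigma2)

    def test_null_chain_draws_match_conjugate_posterior(self, rng):
        x = rng.normal(0, 0.5, size=60)
        data = GCNSignal(np.arange(1, 61), x)
        hp = Hyperparameters(alpha=1.0, beta=1.0)
        cfg = SamplerConfig(n_iter=3000, burn_in=0, seed=5, n_chains=1)
        chain = run_gibbs(data, 0, hp, cfg)
        shape, scale = sigma2_conditional(float(np.sum(x**2)), 60, hp)
        analytic_mean = scale / (shape - 1)
        analytic_sd = math.sqrt(scale**2 / ((shape - 1) ** 2 * (shape - 2)))
        se = analytic_sd / math.sqrt(3000)
        assert abs(chain.sigma2.mean() - analytic_mean) < 4 * se

    def test_sweep_is_fast_enough(self, rng):
        """One sweep at M=500, w_max=200 stays well under a second thanks to
        the prefix-sum scan."""
        import time

        sig = simulate_gcn(preset("fig2", seed=1))
        hp = Hyperparameters(w_max=200)
        cfg = SamplerConfig(n_iter=5, burn_in=0, seed=2, n_chains=1)
        run_gibbs(sig, 1, hp, cfg)  # warm the candidate-grid cache
        t0 = time.perf_counter()
        run_gibbs(sig, 1, hp, SamplerConfig(n_iter=10, burn_in=0, seed=3, n_chains=1))
        per_sweep = (time.perf_counter() - t0) / 10
        assert per_sweep < 1.0

    def test_dispersed_chains_agree_on_the_mode(self):
        sig = simulate_gcn(preset("fig2", seed=9))
        modes = []
        for seed in (1, 2, 3):
            cfg = SamplerConfig(n_iter=200, burn_in=50, seed=seed, n_chains=1)
            summ = summarize(run_gibbs(sig, 1, None, cfg))
            modes.append((summ.segments[0].s_mode, summ.segments[0].w_mode))
        assert modes.count(modes[0]) == len(modes)

    def test_segments_stay_sorted_and_disjoint(self, rng):
        sig = simulate_gcn(preset("fig3", seed=4))
        cfg = SamplerConfig(n_iter=30, burn_in=0, seed=8, n_chains=1)
        chain = run_gibbs(sig, 3, None, cfg)
        for t in range(chain.n_iter):
            state = chain.state_at(t)
            assert not state.overlaps()
            starts = [seg.s for seg in state.segments]
            assert starts == sorted(starts)


class TestSummaries:
    def _constant_chain(self):
        T = 20
        return Chain(
            s=np.full((T, 1), 100),
            w=np.full((T, 1), 10),
            a=np.full((T, 1), 1.5),
            sigma2=np.full(T, 0.16),
            loglik=np.zeros(T),
            logpost=np.zeros(T),
            burn_in=5,
            seed=1,
            M=200,
        )

    def test_constant_chain_degenerate(self):
        summ = summarize(self._constant_chain())
        seg = summ.segments[0]
        assert seg.s_sd == 0 and seg.a_sd == 0
        assert seg.a_ci == (1.5, 1.5)
        assert seg.s_mode == 100 and seg.e_mode == 109

    def test_ci_width_is_392_sd(self):
        sig = simulate_gcn(preset("fig2", seed=3))
        cfg = SamplerConfig(n_iter=300, burn_in=100, seed=3, n_chains=1)
        summ = summarize(run_gibbs(sig, 1, None, cfg))
        seg = summ.segments[0]
        width = seg.a_ci[1] - seg.a_ci[0]
        assert width == pytest.approx(2 * 1.96 * seg.a_sd, rel=1e-9)
        assert seg.a_ci[0] <= seg.a_mean <= seg.a_ci[1]

    def test_burn_in_exhausting_chain_raises(self):
        chain = self._constant_chain()
        with pytest.raises(ValueError):
            summarize(chain, burn_in=20)

    def test_inclusion_frequency_bounds(self):
        chain = self._constant_chain()
        freq = inclusion_frequency(chain)
        assert freq.shape == (200,)
        assert np.all(freq[99:109] == 1.0)
        assert freq.sum() == pytest.approx(10.0)


class TestParameterRecovery:
    def test_single_cnv_recovery_across_replicates(self):
        """Across 50 simulated replicates of the one-CNV setting the modal
        (s, w) lands within one probe of (200, 50) in >= 95% of replicates
        (boundary probes are genuinely ambiguous at this noise level, so
        exactness is only required in >= 85%), and the amplitude credible
        interval covers the true 1.5 in >= 85%."""
        hp = Hyperparameters(w_max=200)
        exact = near = covered = 0
        n_rep = 50
        for rep in range(n_rep):
            sig = simulate_gcn(preset("fig2", seed=3000 + rep))
            cfg = SamplerConfig(n_iter=220, burn_in=60, seed=rep, n_chains=1)
            summ = summarize(run_gibbs(sig, 1, hp, cfg))
            seg = summ.segments[0]
            exact += (seg.s_mode, seg.w_mode) == (200, 50)
            near += abs(seg.s_mode - 200) <= 1 and abs(seg.w_mode - 50) <= 1
            covered += seg.a_ci[0] <= 1.5 <= seg.a_ci[1]
        assert near >= 0.95 * n_rep
        assert exact >= 0.85 * n_rep
        assert covered >= 0.85 * n_rep
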