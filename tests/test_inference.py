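"""Core inference: likelihoods, recursive Bayes update, decision rule, calibration."""

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import logsumexp

from rmsprt.evidence import Condition, error_rate_target, sample_evidence
from rmsprt.inference import (
    CalibrationError,
    DecisionEvaluator,
    NonTerminationError,
    PosteriorState,
    calibrate_threshold,
    decide,
    likelihood_coefficients,
    recursive_update,
    run_msprt_trial,
    run_trial,
    simplified_log_likelihood,
    wald_information_bits,
)
from rmsprt.parameters import (
    ChannelPair,
    IsiStatistics,
    ParameterSet,
    lognormal_shape,
)


def _lognorm_logpdf(x, shape):
    return stats.norm.logpdf(np.log(x), shape.kappa, shape.theta) - np.log(x)


def _equal_stats_registry():
    pair = ChannelPair(IsiStatistics(50.0, 30.0), IsiStatistics(50.0, 30.0))
    return {"flat": ParameterSet("flat", {"25.6": pair}, {})}


def _batch_posterior_from_densities(observations, pref, null, priors):
    """Single-shot Bayes posterior evaluated from the raw channel densities."""
    n, t = observations.shape
    logp = np.zeros(n)
    for i in range(n):
        ll = 0.0
        for k in range(n):
            shape = pref if k == i else null
            ll += _lognorm_logpdf(observations[k], shape).sum()
        logp[i] = math.log(priors[i]) + ll
    return -(logp - logsumexp(logp))


class TestLikelihoodCoefficients:
    def test_indistinguishable_hypotheses_give_zero(self):
        sh = lognormal_shape(IsiStatistics(40.0, 20.0))
        c = likelihood_coefficients(sh, sh)
        assert c.g0 == c.g1 == c.g2 == 0.0

    def test_quadratic_matches_density_ratio(self, registry, rng):
        pair = registry["omega"].get("51.2")
        pref = lognormal_shape(pair.preferred, 40.0)
        null = lognormal_shape(pair.null, 40.0)
        c = likelihood_coefficients(pref, null)
        u = rng.uniform(0.05, 5.0, size=200)
        lhs = c.g0 + c.g1 * np.log(u) ** 2 + c.g2 * np.log(u)
        rhs = _lognorm_logpdf(u, pref) - _lognorm_logpdf(u, null)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_swapping_hypotheses_flips_curvature(self, registry):
        pair = registry["omega"].get("25.6")
        pref = lognormal_shape(pair.preferred)
        null = lognormal_shape(pair.null)
        assert likelihood_coefficients(pref, null).g1 == pytest.approx(
            -likelihood_coefficients(null, pref).g1, rel=1e-12
        )


class TestSimplifiedLogLikelihood:
    def test_unit_observations_give_zero(self, registry):
        pair = registry["omega"].get("25.6")
        c = likelihood_coefficients(
            lognormal_shape(pair.preferred), lognormal_shape(pair.null)
        )
        y = simplified_log_likelihood(np.ones((3, 7)), c)
        np.testing.assert_allclose(y, 0.0)

    def test_equals_summed_density_ratio_plus_constant(self, registry, rng):
        pair = registry["omega"].get("12.8")
        pref = lognormal_shape(pair.preferred, 40.0)
        null = lognormal_shape(pair.null, 40.0)
        c = likelihood_coefficients(pref, null)
        w = 9
        obs = rng.lognormal(null.kappa, null.theta, size=(2, w))
        y = simplified_log_likelihood(obs, c)
        direct = (_lognorm_logpdf(obs, pref) - _lognorm_logpdf(obs, null)).sum(axis=1)
        np.testing.assert_allclose(y + c.g0 * w, direct, atol=1e-10)

    def test_nonpositive_observation_rejected(self, registry):
        pair = registry["omega"].get("12.8")
        c = likelihood_coefficients(
            lognormal_shape(pair.preferred), lognormal_shape(pair.null)
        )
        with pytest.raises(ValueError):
            simplified_log_likelihood(np.array([[1.0, -2.0]]), c)


class TestRecursiveUpdate:
    def test_symmetric_first_step(self):
        state = PosteriorState.from_priors(np.array([0.5, 0.5]), delta=2)
        state = recursive_update(state, np.array([1.3, 1.3]), 0.0, [0.5, 0.5], 2)
        np.testing.assert_allclose(state.neglog_posteriors, math.log(2))

    def test_closed_form_two_hypotheses_and_baseline_cancellation(self):
        a, b = 0.8, -0.4
        for c in (0.0, 17.5, -3.0):
            state = PosteriorState.from_priors(np.array([0.5, 0.5]), delta=3)
            state = recursive_update(state, np.array([a, b]), c, [0.5, 0.5], 3)
            expected = -a + math.log(math.exp(a) + math.exp(b))
            assert state.neglog_posteriors[0] == pytest.approx(expected, abs=1e-12)

    def test_buffer_underrun_detected(self):
        state = PosteriorState.from_priors(np.array([0.5, 0.5]), delta=3)
        state.t = 5  # claim to be past the delay without having filled the buffer
        with pytest.raises(RuntimeError, match="underrun"):
            recursive_update(state, np.zeros(2), 0.0, [0.5, 0.5], 3)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        delta=st.integers(1, 5),
        n=st.sampled_from([2, 3, 4]),
        steps=st.integers(1, 25),
    )
    def test_posteriors_normalised_every_step(self, seed, delta, n, steps):
        rng = np.random.default_rng(seed)
        priors = rng.dirichlet(np.ones(n) * 3)
        state = PosteriorState.from_priors(priors, delta)
        window = deque(maxlen=delta)
        for _ in range(steps):
            y = rng.normal(size=n)
            state = recursive_update(state, y, rng.normal(), priors, delta)
            assert np.exp(-state.neglog_posteriors).sum() == pytest.approx(
                1.0, abs=1e-10
            )
            assert np.all(state.neglog_posteriors >= -1e-12)


class TestEquivalences:
    """Recursive, batch and non-recursive posteriors agree on any stream."""

    @pytest.mark.parametrize("n_alt,coh", [(2, "25.6"), (4, "12.8")])
    @pytest.mark.parametrize("delta", [1, 3, 6])
    def test_recursive_equals_batch_density_posterior(
        self, registry, n_alt, coh, delta
    ):
        cond = Condition(n_alt, coh, "omega", 40.0, correct_channel=1)
        pref, null = cond.shapes()
        rng = np.random.default_rng(delta * 100 + n_alt)
        ev = sample_evidence(cond, 200, rng).observations
        _, rec = run_trial(
            cond, theta=1e-12, rng=np.random.default_rng(0), delta=delta,
            record=True, evidence=ev,
        )
        priors = np.full(n_alt, 1.0 / n_alt)
        for t in (1, 5, delta, delta + 1, 20, rec.neglog_posteriors.shape[0]):
            if t > rec.neglog_posteriors.shape[0]:
                continue
            oracle = _batch_posterior_from_densities(ev[:, :t], pref, null, priors)
            np.testing.assert_allclose(
                rec.neglog_posteriors[t - 1], oracle, atol=1e-10
            )

    def test_recursive_equals_nonrecursive_sequence(self, registry):
        cond = Condition(2, "25.6", "omega", 40.0, correct_channel=2)
        ev = sample_evidence(cond, 60, np.random.default_rng(3)).observations
        o_r, rec_r = run_trial(
            cond, 0.05, np.random.default_rng(1), delta=3, record=True, evidence=ev
        )
        o_m, rec_m = run_msprt_trial(
            cond, 0.05, np.random.default_rng(1), record=True, evidence=ev
        )
        assert (o_r.T, o_r.choice) == (o_m.T, o_m.choice)
        np.testing.assert_allclose(
            rec_r.neglog_posteriors, rec_m.neglog_posteriors, atol=1e-10
        )

    def test_delta_invariance_of_posteriors(self, registry):
        cond = Condition(2, "12.8", "omega", 40.0, correct_channel=1)
        ev = sample_evidence(cond, 80, np.random.default_rng(11)).observations
        base = None
        for delta in (1, 2, 3, 5, 8):
            _, rec = run_trial(
                cond, 0.02, np.random.default_rng(0), delta=delta,
                record=True, evidence=ev,
            )
            if base is None:
                base = rec.neglog_posteriors
            else:
                m = min(len(base), len(rec.neglog_posteriors))
                np.testing.assert_allclose(
                    rec.neglog_posteriors[:m], base[:m], atol=1e-10
                )

    def test_time_varying_baseline_has_no_effect(self, registry):
        cond = Condition(3, "25.6", "omega", 40.0, correct_channel=1)
        # Condition accepts any N >= 2; N=3 exercises the general machinery
        pref, null = cond.shapes()
        coeffs = likelihood_coefficients(pref, null)
        ev = sample_evidence(cond, 30, np.random.default_rng(5)).observations
        rng_c = np.random.default_rng(9)
        priors = np.full(3, 1.0 / 3)
        results = []
        for use_baseline in (False, True):
            state = PosteriorState.from_priors(priors, 3)
            window = deque(maxlen=3)
            trace = []
            for t in range(30):
                window.append(np.log(ev[:, t]))
                y = simplified_log_likelihood(np.exp(np.stack(window, axis=1)), coeffs)
                c = float(rng_c.normal(15.0, 5.0)) if use_baseline else 0.0
                state = recursive_update(state, y, c, priors, 3)
                trace.append(state.neglog_posteriors.copy())
            results.append(np.array(trace))
        np.testing.assert_allclose(results[0], results[1], atol=1e-10)

    def test_data_scaling_invariance(self, registry):
        raw = sample_evidence(
            Condition(2, "25.6", "omega", 1.0, correct_channel=1),
            50,
            np.random.default_rng(21),
        ).observations  # unscaled ISIs (ms)
        cond1 = Condition(2, "25.6", "omega", 1.0, correct_channel=1)
        cond40 = Condition(2, "25.6", "omega", 40.0, correct_channel=1)
        _, rec1 = run_trial(
            cond1, 0.05, np.random.default_rng(0), record=True, evidence=raw
        )
        _, rec40 = run_trial(
            cond40, 0.05, np.random.default_rng(0), record=True, evidence=raw / 40.0
        )
        np.testing.assert_allclose(
            rec1.neglog_posteriors, rec40.neglog_posteriors, atol=1e-10
        )

    def test_two_alternative_reduction_to_wald_sprt(self, registry):
        cond = Condition(2, "25.6", "omega", 40.0, correct_channel=1)
        pref, null = cond.shapes()
        ev = sample_evidence(cond, 40, np.random.default_rng(2)).observations
        _, rec = run_msprt_trial(
            cond, 1e-12, np.random.default_rng(0), record=True, evidence=ev,
        )
        llr = (_lognorm_logpdf(ev, pref) - _lognorm_logpdf(ev, null))
        wald = np.cumsum(llr[0] - llr[1])[: rec.neglog_posteriors.shape[0]]
        diff = rec.neglog_posteriors[:, 0] - rec.neglog_posteriors[:, 1]
        np.testing.assert_allclose(diff, -wald, atol=1e-10)

    def test_msprt_flat_prior_start(self):
        state = PosteriorState.from_priors(np.full(4, 0.25), delta=3)
        np.testing.assert_allclose(state.neglog_posteriors, math.log(4))


class TestDecide:
    def test_threshold_at_log_n_decides_immediately(self, rng):
        state = PosteriorState.from_priors(np.array([0.5, 0.5]), 3)
        out = decide(state, math.log(2), rng)
        assert out.decided and out.T == 0

    def test_above_threshold_continues(self):
        state = PosteriorState.from_priors(np.array([0.5, 0.5]), 3)
        out = decide(state, 0.3)
        assert out.status == "continue" and out.choice is None

    def test_tie_break_is_seeded_and_repeatable(self):
        state = PosteriorState.from_priors(np.full(4, 0.25), 3)
        picks = {decide(state, math.log(4), np.random.default_rng(5)).choice
                 for _ in range(5)}
        assert len(picks) == 1
        many = {decide(state, math.log(4), np.random.default_rng(s)).choice
                for s in range(40)}
        assert len(many) > 1  # different seeds can break the tie differently

    def test_theta_out_of_range_rejected(self):
        state = PosteriorState.from_priors(np.array([0.5, 0.5]), 3)
        for bad in (0.0, -0.1, math.log(2) + 0.2):
            with pytest.raises(ValueError):
                decide(state, bad)

    def test_per_hypothesis_thresholds(self):
        state = PosteriorState.from_priors(np.array([0.5, 0.5]), 3)
        state.neglog_posteriors = np.array([0.4, 1.2])
        # scalar threshold below both: continue
        assert decide(state, 0.3).status == "continue"
        # vector: only hypothesis 1's bound reached
        out = decide(state, np.array([0.5, 0.1]))
        assert out.decided and out.choice == 1
        with pytest.raises(ValueError):
            decide(state, np.array([0.5, 0.1, 0.2]))


class TestTrialRunners:
    def test_identical_distributions_freeze_inference(self):
        cond = Condition(
            2, "25.6", "flat", 1.0, correct_channel=1,
            registry=_equal_stats_registry(),
        )
        with pytest.raises(NonTerminationError):
            run_trial(cond, 0.3, np.random.default_rng(0), step_cap=200)

    def test_chance_accuracy_at_boundary_threshold(self):
        cond = Condition(2, "25.6", "omega", 40.0)
        ev = DecisionEvaluator(cond, 10_000, 13)
        T, choice, correct = ev.decision_stats(math.log(2))
        assert np.all(T == 0)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= correct.sum() <= hi

    def test_vectorised_evaluator_agrees_with_scalar_runner(self):
        cond = Condition(2, "25.6", "omega", 40.0, correct_channel=1)
        theta = 0.1
        rng = np.random.default_rng(77)
        outs = [run_trial(cond, theta, rng)[0] for _ in range(2000)]
        T_s = np.array([o.T for o in outs])
        err_s = np.mean([o.choice != 1 for o in outs])
        ev = DecisionEvaluator(cond, 40_000, 123)
        T_v, _, corr_v = ev.decision_stats(theta)
        err_v = 1.0 - corr_v.mean()
        assert err_s == pytest.approx(err_v, abs=3.5 * math.sqrt(0.05 / 2000))
        assert T_s.mean() == pytest.approx(
            T_v.mean(), abs=4 * T_s.std() / math.sqrt(2000)
        )

    def test_mean_decision_time_decreases_with_coherence(self, registry):
        # matched threshold across coherences isolates the information effect
        means = []
        for coh in ("3.2", "12.8", "51.2"):
            cond = Condition(2, coh, "omega", 40.0)
            ev = DecisionEvaluator(cond, 10_000, 5)
            T, _, correct = ev.decision_stats(0.1)
            means.append(T[correct].mean())
        assert means[0] > means[1] > means[2]


class TestCalibration:
    def test_calibrated_error_rate_matches_target(self):
        cond = Condition(2, "25.6", "omega", 40.0)
        target = error_rate_target(25.6, 2)
        theta = calibrate_threshold(cond, target, 10_000, 42)
        fresh = DecisionEvaluator(cond, 10_000, 4242)
        _, _, correct = fresh.decision_stats(theta)
        lo, hi = stats.binom.interval(0.99, 10_000, target)
        assert lo <= (10_000 - correct.sum()) <= hi

    def test_lower_error_target_needs_more_evidence(self):
        cond = Condition(2, "12.8", "omega", 40.0)
        th_loose = calibrate_threshold(cond, 0.2, 5_000, 1)
        th_tight = calibrate_threshold(cond, 0.02, 5_000, 1)
        assert th_tight < th_loose
        ev = DecisionEvaluator(cond, 10_000, 2)
        T_loose, _, _ = ev.decision_stats(th_loose)
        T_tight, _, _ = ev.decision_stats(th_tight)
        assert T_tight.mean() > T_loose.mean()

    def test_chance_target_returns_boundary_threshold(self):
        cond = Condition(2, "25.6", "omega", 40.0)
        assert calibrate_threshold(cond, 0.5, 100, 0) == pytest.approx(math.log(2))

    def test_out_of_range_target_rejected(self):
        cond = Condition(2, "25.6", "omega", 40.0)
        for bad in (0.0, 0.7, 1.0):
            with pytest.raises(CalibrationError):
                calibrate_threshold(cond, bad, 100, 0)

    def test_unattainable_target_raises(self):
        cond = Condition(
            2, "25.6", "flat", 1.0, registry=_equal_stats_registry()
        )
        with pytest.raises(CalibrationError, match="unattainable"):
            calibrate_threshold(cond, 0.1, 200, 0, step_cap=96)

    def test_empirical_sample_size_respects_information_bound(self):
        # With two channels the per-observation discrimination between the
        # joint hypotheses is the symmetrised divergence KL(f*||f0) +
        # KL(f0||f*); Wald's information inequality bounds E[T] from below
        # by the required total information over that per-step amount.
        from rmsprt.parameters import kl_divergence_bits

        cond = Condition(2, "25.6", "omega", 40.0)
        target = error_rate_target(25.6, 2)
        theta = calibrate_threshold(cond, target, 10_000, 9)
        ev = DecisionEvaluator(cond, 20_000, 99)
        T, _, correct = ev.decision_stats(theta)
        eps_hat = 1.0 - correct.mean()
        pref, null = cond.shapes()
        per_step_bits = kl_divergence_bits(pref, null) + kl_divergence_bits(null, pref)
        bound = wald_information_bits(eps_hat) / per_step_bits
        se = T.std() / math.sqrt(T.size)
        assert T.mean() >= bound - 3 * se
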