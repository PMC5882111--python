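"""Core of the recursive multi-hypothesis sequential probability ratio test.

The test tracks, for each of ``N`` hypotheses, the negative log-posterior
given all evidence so far.  Evidence enters through a "simplified"
log-likelihood: for lognormal channel densities the per-observation
log-density-ratio is a quadratic in the log observation,

    log f*(u) - log f0(u) = g0 + g1 (log u)^2 + g2 log u,

and the hypothesis-independent ``g0`` terms cancel under posterior
normalisation, so only the ``g1``/``g2`` sums are accumulated.  The update
is a generalized, delayed-feedback form of Bayes' rule: for the first
``delta`` steps the fixed initial priors are used with the likelihood of the
full history; afterwards the posterior from ``delta`` steps in the past is
fed back as the prior, combined with the likelihood of only the most recent
``delta`` observations.  Because a posterior is a sufficient statistic of
the evidence it has absorbed, the recursive posterior equals the single-shot
(batch) Bayes posterior at every step, and hence also the classic
non-recursive test (the ``delta -> infinity`` special case).  A decision is
made the first time the smallest negative log-posterior falls to a constant
threshold ``theta`` in ``(0, log N]``.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .evidence import Condition
from .parameters import LognormalShape

__all__ = [
    "LikelihoodCoefficients",
    "LoopLatencies",
    "PosteriorState",
    "DecisionOutcome",
    "TrialRecord",
    "CalibrationError",
    "NonTerminationError",
    "likelihood_coefficients",
    "simplified_log_likelihood",
    "recursive_update",
    "decide",
    "run_trial",
    "run_msprt_trial",
    "DecisionEvaluator",
    "calibrate_threshold",
    "wald_information_bits",
]

DEFAULT_STEP_CAP = 100_000


class CalibrationError(RuntimeError):
    """Raised when no threshold in (0, log N] attains the target error rate."""


class NonTerminationError(RuntimeError):
    """Raised when a trial exceeds the step cap without crossing the threshold."""


@dataclass(frozen=True)
class LikelihoodCoefficients:
    """Coefficients of the per-observation log-density-ratio quadratic.

    ``g0`` is carried only for oracle checks; inference drops it because it
    is hypothesis-independent.
    """

    g1: float
    g2: float
    g0: float


@dataclass(frozen=True)
class LoopLatencies:
    """Integer signal latencies around the cortex -> basal ganglia -> thalamus loop.

    ``delta_yb``: cortex to basal ganglia; ``delta_bu``: basal ganglia to
    thalamus; ``delta_uy``: thalamus to cortex; ``delta_yu``: cortex to
    thalamus (the diffuse baseline projection).  The recursion delay is
    ``Delta = delta_yb + delta_bu + delta_uy`` and must be >= 1.
    """

    delta_yb: int = 1
    delta_bu: int = 1
    delta_uy: int = 1
    delta_yu: int = 1

    def __post_init__(self) -> None:
        for name in ("delta_yb", "delta_bu", "delta_uy", "delta_yu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.total < 1:
            raise ValueError("total recursion delay Delta must be >= 1")

    @property
    def total(self) -> int:
        return self.delta_yb + self.delta_bu + self.delta_uy


@dataclass
class PosteriorState:
    """Negative log-posteriors plus the feedback buffer and likelihood window.

    ``buffer`` holds the neglog-posterior vectors of the last ``delta`` time
    steps (oldest first; seeded with the time-0 prior), so at the update to
    time ``t`` the vector from ``t - delta`` is ``buffer[0]`` once
    ``t > delta``.  ``window`` holds the
    log-observations (channels x steps) of the active likelihood window.
    """

    neglog_posteriors: np.ndarray
    buffer: deque = field(repr=False)
    window: deque = field(repr=False)
    t: int = 0

    @property
    def posteriors(self) -> np.ndarray:
        return np.exp(-self.neglog_posteriors)

    @classmethod
    def from_priors(cls, priors: np.ndarray, delta: int) -> "PosteriorState":
        priors = np.asarray(priors, dtype=float)
        if abs(priors.sum() - 1.0) > 1e-10 or np.any(priors <= 0):
            raise ValueError("priors must be strictly positive and sum to 1")
        neglog = -np.log(priors)
        return cls(
            neglog_posteriors=neglog,
            buffer=deque([neglog.copy()], maxlen=delta),
            window=deque(maxlen=delta),
        )


def likelihood_coefficients(
    pref: LognormalShape, null: LognormalShape
) -> LikelihoodCoefficients:
    """Quadratic coefficients of ``log f*(u) - log f0(u)`` for lognormal densities."""
    t2p, t2n = pref.theta2, null.theta2
    g1 = 1.0 / (2.0 * t2n) - 1.0 / (2.0 * t2p)
    g2 = pref.kappa / t2p - null.kappa / t2n
    g0 = (
        null.kappa**2 / (2.0 * t2n)
        - pref.kappa**2 / (2.0 * t2p)
        + 0.5 * math.log(t2n / t2p)
    )
    return LikelihoodCoefficients(g1=g1, g2=g2, g0=g0)


def simplified_log_likelihood(
    window_obs: np.ndarray, coeffs: LikelihoodCoefficients
) -> np.ndarray:
    """Per-hypothesis simplified log-likelihood over the active window.

    ``window_obs`` is (channels x window) of scaled, strictly positive
    observations; returns ``y_i = g1 sum (log x_i)^2 + g2 sum log x_i``.
    """
    obs = np.asarray(window_obs, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observations must be strictly positive")
    logx = np.log(obs)
    return coeffs.g1 * (logx**2).sum(axis=-1) + coeffs.g2 * logx.sum(axis=-1)


def recursive_update(
    state: PosteriorState,
    y: np.ndarray,
    baseline_c: float,
    priors: np.ndarray,
    delta: int,
) -> PosteriorState:
    """Advance the negative log-posteriors by one step (delayed-feedback Bayes).

    For ``t <= delta`` the fixed ``priors`` are used (``y`` must then cover
    observations ``1..t``); for ``t > delta`` the neglog posterior from
    ``delta`` steps back replaces them (``y`` covers the last ``delta``
    observations).  The hypothesis-independent ``baseline_c`` provably
    cancels in the normalisation.
    """
    t_new = state.t + 1
    if t_new <= delta:
        log_prior = np.log(np.asarray(priors, dtype=float))
    else:
        if len(state.buffer) < delta:
            raise RuntimeError(
                f"posterior buffer underrun at t={t_new}: have "
                f"{len(state.buffer)} entries, need {delta}"
            )
        log_prior = -state.buffer[0]
    v = np.asarray(y, dtype=float) + baseline_c + log_prior
    neglog = -v + logsumexp(v)
    state.buffer.append(neglog.copy())
    state.neglog_posteriors = neglog
    state.t = t_new
    return state


@dataclass(frozen=True)
class DecisionOutcome:
    """Result of testing the posteriors against the threshold."""

    status: str  # "continue" or "decided"
    choice: int | None  # 1-based hypothesis index
    T: int  # decision sample size (steps)

    @property
    def decided(self) -> bool:
        return self.status == "decided"


def decide(
    state: PosteriorState,
    theta: float | np.ndarray,
    rng: np.random.Generator | None = None,
) -> DecisionOutcome:
    """Apply the threshold rule: choose the min neglog-posterior if it is <= theta.

    ``theta`` must lie in ``(0, log N]``.  A vector of per-hypothesis
    thresholds ``(theta_1, ..., theta_N)`` is also accepted (the more
    general formulation: hypothesis ``i`` can terminate the trial once its
    neglog posterior reaches ``theta_i``; among the hypotheses at bound,
    the most probable is chosen).  Exact ties are broken uniformly with
    ``rng`` (first index if no generator is given).
    """
    neglog = state.neglog_posteriors
    n = neglog.size
    if np.ndim(theta) == 0:
        _check_theta(float(theta), n)
        at_bound = neglog <= theta
    else:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (n,):
            raise ValueError(f"need one threshold per hypothesis, got {theta.shape}")
        for th in theta:
            _check_theta(float(th), n)
        at_bound = neglog <= theta
    if not at_bound.any():
        return DecisionOutcome(status="continue", choice=None, T=state.t)
    m = neglog[at_bound].min()
    ties = np.flatnonzero(at_bound & (neglog == m))
    if ties.size == 1 or rng is None:
        idx = ties[0]
    else:
        idx = rng.choice(ties)
    return DecisionOutcome(status="decided", choice=int(idx) + 1, T=state.t)


def _check_theta(theta: float, n: int) -> None:
    if not (0.0 < theta <= math.log(n) + 1e-12):
        raise ValueError(
            f"theta must be in (0, log N] = (0, {math.log(n):.6f}], got {theta}"
        )


@dataclass
class TrialRecord:
    """Per-step record of a trial: observations, likelihoods and posteriors."""

    observations: np.ndarray  # channels x T
    y: np.ndarray  # T x N simplified log-likelihoods
    neglog_posteriors: np.ndarray  # T x N
    correct_channel: int


def _draw_step(condition: Condition, correct: int, rng: np.random.Generator):
    pref, null = condition.shapes()
    kappas = np.full(condition.n_alternatives, null.kappa)
    thetas = np.full(condition.n_alternatives, null.theta)
    kappas[correct - 1] = pref.kappa
    thetas[correct - 1] = pref.theta
    return np.exp(rng.normal(kappas, thetas))


def run_trial(
    condition: Condition,
    theta: float,
    rng: np.random.Generator,
    delta: int | LoopLatencies = 3,
    priors: np.ndarray | None = None,
    baseline_c: float = 0.0,
    step_cap: int = DEFAULT_STEP_CAP,
    record: bool = False,
    evidence: np.ndarray | None = None,
) -> tuple[DecisionOutcome, TrialRecord | None]:
    """Run one recursive-test trial until decision.

    Iterates sample -> simplified likelihood -> delayed-feedback update ->
    threshold test.  ``evidence`` may supply a pre-drawn (channels x steps)
    observation block for matched-stream comparisons; otherwise fresh
    observations are drawn from ``rng`` each step.  Returns the decision
    outcome (choice, sample size ``T``) and, if ``record``, the per-step
    trajectories.
    """
    if isinstance(delta, LoopLatencies):
        delta = delta.total
    n = condition.n_alternatives
    _check_theta(theta, n)
    if priors is None:
        priors = np.full(n, 1.0 / n)
    correct = condition.correct_channel or int(rng.integers(1, n + 1))
    pref, null = condition.shapes()
    coeffs = likelihood_coefficients(pref, null)
    state = PosteriorState.from_priors(priors, delta)

    outcome = decide(state, theta, rng)
    rows_obs, rows_y, rows_neglog = [], [], []
    while not outcome.decided:
        if state.t >= step_cap:
            raise NonTerminationError(
                f"no decision after {step_cap} steps (N={n}, "
                f"coherence={condition.coherence}, set={condition.parameter_set}, "
                f"theta={theta}, min neglog={state.neglog_posteriors.min():.4f})"
            )
        if evidence is not None:
            if state.t >= evidence.shape[1]:
                raise NonTerminationError(
                    f"supplied evidence exhausted after {evidence.shape[1]} steps"
                )
            obs = np.asarray(evidence[:, state.t], dtype=float)
        else:
            obs = _draw_step(condition, correct, rng)
        state.window.append(np.log(obs))
        y = _window_y(state.window, coeffs)
        state = recursive_update(state, y, baseline_c, priors, delta)
        outcome = decide(state, theta, rng)
        if record:
            rows_obs.append(obs)
            rows_y.append(y)
            rows_neglog.append(state.neglog_posteriors.copy())
    rec = None
    if record:
        rec = TrialRecord(
            observations=np.array(rows_obs).T if rows_obs else np.empty((n, 0)),
            y=np.array(rows_y) if rows_y else np.empty((0, n)),
            neglog_posteriors=(
                np.array(rows_neglog) if rows_neglog else np.empty((0, n))
            ),
            correct_channel=correct,
        )
    return outcome, rec


def _window_y(window: deque, coeffs: LikelihoodCoefficients) -> np.ndarray:
    logx = np.stack(window, axis=1)  # channels x window-length
    return coeffs.g1 * (logx**2).sum(axis=1) + coeffs.g2 * logx.sum(axis=1)


def run_msprt_trial(
    condition: Condition,
    theta: float,
    rng: np.random.Generator,
    priors: np.ndarray | None = None,
    baseline_c: float = 0.0,
    step_cap: int = DEFAULT_STEP_CAP,
    record: bool = False,
    evidence: np.ndarray | None = None,
) -> tuple[DecisionOutcome, TrialRecord | None]:
    """Run one standard, non-recursive test trial (fixed priors, full history).

    The likelihood always covers observations ``1..t`` and the priors are
    never updated — the ``delta -> infinity`` behaviour.  On the same
    evidence stream the posterior sequence is identical to the recursive
    test's.
    """
    n = condition.n_alternatives
    _check_theta(theta, n)
    if priors is None:
        priors = np.full(n, 1.0 / n)
    log_prior = np.log(priors)
    correct = condition.correct_channel or int(rng.integers(1, n + 1))
    pref, null = condition.shapes()
    coeffs = likelihood_coefficients(pref, null)
    s1 = np.zeros(n)
    s2 = np.zeros(n)
    t = 0
    neglog = -log_prior.copy()
    state = PosteriorState(
        neglog_posteriors=neglog, buffer=deque([neglog.copy()]), window=deque()
    )
    outcome = decide(state, theta, rng)
    rows_obs, rows_y, rows_neglog = [], [], []
    while not outcome.decided:
        if t >= step_cap:
            raise NonTerminationError(f"no decision after {step_cap} steps")
        if evidence is not None:
            if t >= evidence.shape[1]:
                raise NonTerminationError("supplied evidence exhausted")
            obs = np.asarray(evidence[:, t], dtype=float)
        else:
            obs = _draw_step(condition, correct, rng)
        logx = np.log(obs)
        s1 += logx
        s2 += logx**2
        y = coeffs.g1 * s2 + coeffs.g2 * s1
        v = y + baseline_c + log_prior
        neglog = -v + logsumexp(v)
        t += 1
        state.neglog_posteriors = neglog
        state.t = t
        outcome = decide(state, theta, rng)
        if record:
            rows_obs.append(obs)
            rows_y.append(y.copy())
            rows_neglog.append(neglog.copy())
    rec = None
    if record:
        rec = TrialRecord(
            observations=np.array(rows_obs).T if rows_obs else np.empty((n, 0)),
            y=np.array(rows_y) if rows_y else np.empty((0, n)),
            neglog_posteriors=(
                np.array(rows_neglog) if rows_neglog else np.empty((0, n))
            ),
            correct_channel=correct,
        )
    return outcome, rec


class DecisionEvaluator:
    """Vectorised many-trial decision evaluator with common random numbers.

    Simulates a batch of trials of one condition by accumulating the
    cumulative log-likelihood statistic per channel (valid because the
    recursive posterior equals the batch posterior at every step — verified
    against :func:`run_trial` in the test suite).  The evidence tensor is
    drawn once and lazily extended, so decision statistics can be evaluated
    for many candidate thresholds on identical streams — the common random
    numbers needed for threshold calibration.
    """

    def __init__(
        self,
        condition: Condition,
        n_trials: int,
        seed: int | np.random.Generator,
        priors: np.ndarray | None = None,
        step_cap: int = DEFAULT_STEP_CAP,
        initial_steps: int = 16,
    ) -> None:
        self.condition = condition
        self.n_trials = int(n_trials)
        self.n = condition.n_alternatives
        self.step_cap = step_cap
        self.rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        if priors is None:
            priors = np.full(self.n, 1.0 / self.n)
        self.log_prior = np.log(np.asarray(priors, dtype=float))
        pref, null = condition.shapes()
        self._pref, self._null = pref, null
        self.coeffs = likelihood_coefficients(pref, null)
        if condition.correct_channel is None:
            self.correct_channel = self.rng.integers(
                1, self.n + 1, size=self.n_trials
            )
        else:
            self.correct_channel = np.full(
                self.n_trials, condition.correct_channel, dtype=int
            )
        self._s1 = np.zeros((self.n_trials, self.n), dtype=np.float32)
        self._s2 = np.zeros((self.n_trials, self.n), dtype=np.float32)
        # m[t]: min neglog posterior after step t+1; a[t]: its argmin.
        # float32 suffices: m only feeds threshold comparisons.
        self._m = np.empty((self.n_trials, 0), dtype=np.float32)
        self._a = np.empty((self.n_trials, 0), dtype=np.int8)
        self._chunk = 32  # extension chunk cap bounds transient memory
        self._extend(initial_steps)

    @property
    def steps_available(self) -> int:
        return self._m.shape[1]

    def _extend(self, n_steps: int) -> None:
        b, n = self.n_trials, self.n
        rows = np.arange(b)
        while n_steps > 0:
            steps = min(n_steps, self._chunk)
            n_steps -= steps
            # float32 throughout: the evaluator feeds Monte Carlo statistics
            # (calibration, behaviour summaries), where sampling noise
            # dwarfs single precision; exact-arithmetic checks use the
            # scalar runners.
            logx = self.rng.standard_normal((b, n, steps), dtype=np.float32)
            logx *= np.float32(self._null.theta)
            logx += np.float32(self._null.kappa)
            pref_draws = self.rng.standard_normal((b, steps), dtype=np.float32)
            pref_draws *= np.float32(self._pref.theta)
            pref_draws += np.float32(self._pref.kappa)
            logx[rows, self.correct_channel - 1, :] = pref_draws
            cs1 = self._s1[:, :, None] + np.cumsum(logx, axis=2)
            np.square(logx, out=logx)
            cs2 = self._s2[:, :, None] + np.cumsum(logx, axis=2)
            del logx
            self._s1 = cs1[:, :, -1].copy()
            self._s2 = cs2[:, :, -1].copy()
            cs2 *= self.coeffs.g1
            cs1 *= self.coeffs.g2
            L = cs2
            L += cs1
            del cs1
            L += self.log_prior[None, :, None].astype(L.dtype)
            # min_i neglogP_i = logsumexp_j L_j - max_i L_i ; argmin = argmax L
            lse = logsumexp(L, axis=1)
            mx = L.max(axis=1)
            a = L.argmax(axis=1).astype(np.int8)
            del L
            self._m = np.concatenate(
                [self._m, (lse - mx).astype(np.float32)], axis=1
            )
            self._a = np.concatenate([self._a, a], axis=1)

    def decision_stats(self, theta: float):
        """(T, choice, correct) arrays for threshold ``theta`` on the common streams."""
        _check_theta(theta, self.n)
        if theta >= math.log(self.n) - 1e-12:
            # flat priors already at threshold: immediate uniform guess
            choice = self.rng.integers(1, self.n + 1, size=self.n_trials)
            T = np.zeros(self.n_trials, dtype=int)
            return T, choice, choice == self.correct_channel
        while True:
            crossed = self._m <= theta
            if crossed.any(axis=1).all():
                break
            if self.steps_available >= self.step_cap:
                n_bad = int((~crossed.any(axis=1)).sum())
                raise NonTerminationError(
                    f"{n_bad} of {self.n_trials} trials undecided after "
                    f"{self.steps_available} steps at theta={theta}"
                )
            self._extend(min(self._chunk, self.step_cap - self.steps_available))
        first = crossed.argmax(axis=1)
        T = first + 1
        choice = self._a[np.arange(self.n_trials), first].astype(int) + 1
        return T, choice, choice == self.correct_channel

    def error_rate(self, theta: float) -> float:
        _, _, correct = self.decision_stats(theta)
        return 1.0 - float(correct.mean())

    def error_rate_curve(self):
        """Exact error rate as a step function of the threshold on these streams.

        For each trial the decision time at threshold ``theta`` is the first
        step where the neglog-posterior minimum reaches ``theta``; only the
        strictly-new running minima of that trajectory can be decision
        points, so correctness per trial is piecewise constant in ``theta``
        with breakpoints at those minima.  Returns ``(thetas, eps,
        theta_cover)``: descending breakpoints, the error-rate estimate on
        the interval *below* each breakpoint, and the smallest threshold
        for which every trial has crossed within the steps simulated so far
        (the curve is only valid for ``theta >= theta_cover``).
        """
        m = self._m
        b = self.n_trials
        prev = np.concatenate(
            [np.full((b, 1), np.inf, dtype=m.dtype),
             np.minimum.accumulate(m, axis=1)[:, :-1]],
            axis=1,
        )
        is_event = m < prev
        trial_idx, step_idx = np.nonzero(is_event)
        values = m[trial_idx, step_idx].astype(np.float64)
        correct = (
            self._a[trial_idx, step_idx].astype(int) + 1
            == self.correct_channel[trial_idx]
        )
        theta_cover = float(np.minimum.accumulate(m, axis=1)[:, -1].max())
        # per trial, events are in time order with strictly decreasing value;
        # at theta just below a breakpoint the decision moves to the next event
        first_event = np.concatenate([[True], trial_idx[1:] != trial_idx[:-1]])
        base_correct = int(correct[first_event].sum())  # theta near log N
        later = ~first_event
        bp_theta = values[:-1][later[1:]] if later.any() else np.empty(0)
        # breakpoint at v_i: for theta < v_i correctness switches to event i+1
        delta = np.where(correct, 1, 0)[1:] - np.where(correct, 1, 0)[:-1]
        bp_delta = delta[later[1:]]
        order = np.argsort(-bp_theta, kind="stable")
        thetas = bp_theta[order]
        n_correct = base_correct + np.concatenate(
            [[0], np.cumsum(bp_delta[order])]
        )
        eps = 1.0 - n_correct / b  # eps[k] holds below thetas[k-1] .. thetas[k]
        return thetas, eps, theta_cover


def calibrate_threshold(
    condition: Condition,
    epsilon_target: float,
    mc_trials: int = 10_000,
    rng: int | np.random.Generator = 0,
    tol: float | None = None,
    step_cap: int = DEFAULT_STEP_CAP,
) -> float:
    """Find the threshold whose Monte Carlo error rate matches ``epsilon_target``.

    Under common random numbers the error rate is an exact step function of
    ``theta`` (see :meth:`DecisionEvaluator.error_rate_curve`), so the
    calibration inverts that curve directly: it picks the threshold
    interval whose error rate is closest to the target, extending the
    simulated streams until the interval is fully covered.  Fails with
    :class:`CalibrationError` when the target stays out of reach within the
    step cap, or is outside ``(0, 1 - 1/N)``.

    The Monte Carlo size is enlarged beyond ``mc_trials`` where needed so
    that the binomial standard error of the estimate is at most half the
    tolerance (default ``min(0.002, 0.15 * target)``) — without this the
    sampling noise of the calibration, not its tolerance, would bound the
    achieved error rate.
    """
    n = condition.n_alternatives
    chance = 1.0 - 1.0 / n
    if abs(epsilon_target - chance) < 1e-12:
        return math.log(n)  # boundary: immediate uniform guessing
    if not 0.0 < epsilon_target < chance:
        raise CalibrationError(
            f"epsilon_target must be in (0, 1 - 1/N) = (0, {chance:.4f}), "
            f"got {epsilon_target}"
        )
    if tol is None:
        tol = min(0.002, 0.15 * epsilon_target)
    needed = 4.0 * epsilon_target * (1.0 - epsilon_target) / tol**2
    trials = max(mc_trials, min(int(math.ceil(needed)), 250_000))
    ev = DecisionEvaluator(condition, trials, rng, step_cap=step_cap)

    log_n = math.log(n)
    while True:
        thetas, eps, cover = ev.error_rate_curve()
        hi_edges = np.concatenate([[log_n], thetas])
        lo_edges = np.concatenate([thetas, [cover]])
        valid = hi_edges > max(cover, 0.0)
        gaps = np.abs(eps - epsilon_target)
        gaps[~valid] = np.inf
        k = int(np.argmin(gaps))
        lowest_valid_eps = eps[valid][-1] if valid.any() else np.inf
        if gaps[k] <= tol or lowest_valid_eps <= epsilon_target:
            # either close enough, or the solution lies within the covered
            # range and this is the closest attainable step
            lo = max(lo_edges[k], cover)
            return float(min(0.5 * (lo + hi_edges[k]), log_n))
        if ev.steps_available >= step_cap:
            raise CalibrationError(
                f"error rate {lowest_valid_eps:.4f} still above target "
                f"{epsilon_target:.4f} at theta={cover:.3e} after "
                f"{ev.steps_available} steps; target unattainable"
            )
        ev._extend(min(ev._chunk, step_cap - ev.steps_available))


def wald_information_bits(epsilon: float) -> float:
    """Expected total discrimination information (bits) for a two-alternative test.

    The classic sequential-test identity: the expected log-likelihood-ratio
    at decision is ``(1 - 2 eps) log((1 - eps)/eps)`` nats for error rate
    ``eps``; returned in bits.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    return (1.0 - 2.0 * epsilon) * math.log2((1.0 - epsilon) / epsilon)
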