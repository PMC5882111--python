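"""Mapping of the recursive test onto the cortico-basal-ganglia-thalamo-cortical loop.

Each inference step decomposes across the loop: sensorimotor cortex holds
the simplified log-likelihood plus the fed-back log-prior and a
hypothesis-independent baseline ``c(t)``; the striatum relays a copy of the
cortical signal; the basal-ganglia output holds the fresh negative
log-posteriors (the decision variables tested against the threshold); and
the thalamus relays the updated log-posterior back to cortex on top of a
diffuse cortico-thalamic baseline ``h(t)``.  All signals are delayed by the
integer latencies of :class:`~rmsprt.inference.LoopLatencies`; the recursion
delay ``Delta`` is their loop total.  The baselines are shaped by two free
parameters — the constant cortical baseline ``l`` and the cortico-thalamic
weight ``w_yu`` — which, being hypothesis-independent, provably leave
inference unchanged; they exist to place the mapped traces in the dynamic
range of recorded firing rates.

Time indexing convention: all series run on the basal-ganglia clock.  Trace
arrays carry a *display step* axis where step ``-1`` is the pre-evidence
step (no inference; determined by initial priors and baselines alone) and
display step ``s >= 0`` corresponds to inference time ``t = s + 1``.  The
first fed-back posterior therefore arrives at display step ``Delta``, which
is where the "fork" between selected and non-selected traces begins.

The exact linear combination displayed per region is a documented
convention (the loop decomposition fixes what each region sums, not the
plotted offsets); the basal-ganglia output is the inference arithmetic
itself and is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .evidence import Condition
from .inference import (
    DEFAULT_STEP_CAP,
    DecisionOutcome,
    LoopLatencies,
    NonTerminationError,
    PosteriorState,
    decide,
    likelihood_coefficients,
    recursive_update,
    _draw_step,
    _window_y,
)

__all__ = [
    "CircuitConfig",
    "CircuitTraces",
    "AveragedTraces",
    "step_circuit",
    "run_trial_with_traces",
    "run_msprt_trial_with_traces",
    "baseline_bg_output",
    "align_and_average_traces",
    "REGIONS",
]

REGIONS = ("cortex", "striatum", "bg_output", "thalamus")


@dataclass(frozen=True)
class CircuitConfig:
    """Free parameters of the circuit mapping (none affects inference)."""

    latencies: LoopLatencies = field(default_factory=LoopLatencies)
    l: float = 15.0
    w_yu: float = 0.4
    post_decision_steps: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_yu < 1.0:
            raise ValueError("w_yu must lie in [0, 1)")
        if self.l < 0:
            raise ValueError("baseline l must be nonnegative")
        lat = self.latencies
        if lat.delta_uy + lat.delta_yu < 1:
            raise ValueError(
                "causality of the cortico-thalamic baseline requires "
                "delta_uy + delta_yu >= 1"
            )

    @property
    def delta(self) -> int:
        return self.latencies.total


@dataclass
class CircuitTraces:
    """Per-region, per-hypothesis time series of one trial on the loop clock.

    Row ``k`` of each array is display step ``steps[k]`` (step -1 first).
    ``h`` entries that would require evidence beyond the recorded horizon
    are NaN.
    """

    steps: np.ndarray
    cortex: np.ndarray
    striatum: np.ndarray
    bg_output: np.ndarray
    thalamus: np.ndarray
    c: np.ndarray
    h: np.ndarray
    choice: int
    correct_channel: int
    T: int

    @property
    def initiation_index(self) -> int:
        return 0  # row of display step -1

    @property
    def termination_index(self) -> int:
        # row of display step T - 1, i.e. inference time T
        return int(np.searchsorted(self.steps, self.T - 1))

    def region(self, name: str) -> np.ndarray:
        if name not in REGIONS:
            raise KeyError(f"unknown region {name!r}; available: {REGIONS}")
        return getattr(self, name)


class _CircuitState:
    """Mutable loop state: posterior machinery plus signal histories."""

    def __init__(
        self,
        condition: Condition,
        config: CircuitConfig,
        priors: np.ndarray | None = None,
    ) -> None:
        self.condition = condition
        self.config = config
        n = condition.n_alternatives
        self.n = n
        self.priors = np.full(n, 1.0 / n) if priors is None else np.asarray(priors, float)
        self.log_prior = np.log(self.priors)
        pref, null = condition.shapes()
        self.coeffs = likelihood_coefficients(pref, null)
        self.delta = config.delta
        self.posterior = PosteriorState.from_priors(self.priors, self.delta)
        # histories on the basal-ganglia clock; pre-evidence values (t <= 0):
        # y = 0, posteriors = priors, h = 0, c = l (so z = l)
        self._z: dict[int, np.ndarray] = {}
        self._logP: dict[int, np.ndarray] = {}
        self._h: dict[int, float] = {}
        self._c: dict[int, float] = {}

    # -- history accessors with pre-evidence defaults ------------------
    def z_at(self, t: int) -> np.ndarray | None:
        if t <= 0:
            return np.full(self.n, self.config.l)
        return self._z.get(t)

    def logP_at(self, t: int) -> np.ndarray:
        if t <= 0:
            return self.log_prior
        return self._logP[t]

    def h_at(self, t: int) -> float:
        """Cortico-thalamic baseline h(t); NaN if it needs unseen evidence."""
        if t <= 0:
            return 0.0
        if t not in self._h:
            lat = self.config.latencies
            z_idx = t + lat.delta_bu + lat.delta_yb - lat.delta_yu
            p_idx = t - lat.delta_uy - lat.delta_yu
            z = self.z_at(z_idx)
            if z is None:
                return math.nan
            self._h[t] = float(
                self.config.w_yu * np.mean(z + self.logP_at(p_idx))
            )
        return self._h[t]

    def c_at(self, t: int) -> float:
        if t <= 0:
            return self.config.l
        if t not in self._c:
            h = self.h_at(t - self.delta)
            if math.isnan(h):  # pragma: no cover - guarded by causality check
                raise RuntimeError(f"baseline c({t}) requires unseen evidence")
            self._c[t] = h + self.config.l
        return self._c[t]

    # -- stepping -------------------------------------------------------
    def step(self, observation: np.ndarray) -> dict:
        """Advance one inference step and return the trace row at the new time."""
        t = self.posterior.t + 1
        c_t = self.c_at(t)
        self.posterior.window.append(np.log(np.asarray(observation, dtype=float)))
        y = _window_y(self.posterior.window, self.coeffs)
        # prior feedback term the cortex sums at this step
        if t <= self.delta:
            fedback = self.log_prior
        else:
            fedback = -self.posterior.buffer[0]
        self.posterior = recursive_update(
            self.posterior, y, c_t, self.priors, self.delta
        )
        z = y + c_t
        self._z[t] = z
        self._logP[t] = -self.posterior.neglog_posteriors
        return self.trace_row(t, z=z, fedback=fedback)

    def trace_row(self, t: int, z: np.ndarray, fedback: np.ndarray) -> dict:
        lat = self.config.latencies
        cortex = z + fedback
        bg = (
            self.posterior.neglog_posteriors
            if t >= 1
            else -self.log_prior
        )
        thalamus = self.h_at(t - lat.delta_uy) + self.logP_at(t - lat.delta_bu)
        return {
            "t": t,
            "cortex": cortex,
            "striatum": cortex.copy(),
            "bg_output": bg.copy() if isinstance(bg, np.ndarray) else bg,
            "thalamus": thalamus,
            "c": self.c_at(t),
            "h": self.h_at(t),
        }

    def pre_evidence_row(self) -> dict:
        # display step -1: no inference, priors and baselines only
        z = np.full(self.n, self.config.l)  # y = 0, c = l
        return self.trace_row(0, z=z, fedback=self.log_prior) | {"t": 0}


def step_circuit(
    state: _CircuitState, new_observation_vector: np.ndarray, config: CircuitConfig
) -> tuple[_CircuitState, dict]:
    """Advance the circuit-mapped state one step; returns (state, trace row).

    Thin functional wrapper over :meth:`_CircuitState.step`; ``config`` must
    be the state's own configuration.
    """
    if config is not state.config:
        raise ValueError("config must be the state's own CircuitConfig")
    row = state.step(new_observation_vector)
    return state, row


def new_circuit_state(
    condition: Condition,
    config: CircuitConfig | None = None,
    priors: np.ndarray | None = None,
) -> _CircuitState:
    return _CircuitState(condition, config or CircuitConfig(), priors)


def run_trial_with_traces(
    condition: Condition,
    theta: float,
    config: CircuitConfig | None = None,
    rng: np.random.Generator | None = None,
    priors: np.ndarray | None = None,
    step_cap: int = DEFAULT_STEP_CAP,
    evidence: np.ndarray | None = None,
) -> tuple[DecisionOutcome, CircuitTraces]:
    """Run one trial on the circuit mapping, recording all region traces.

    The basal-ganglia output follows the exact inference arithmetic (same
    code path as :func:`rmsprt.inference.run_trial`), so the decision and
    sample size are identical to an inference-core run under the same seed;
    the trial continues ``config.post_decision_steps`` beyond threshold
    crossing for termination-aligned averaging.
    """
    config = config or CircuitConfig()
    rng = rng if rng is not None else np.random.default_rng()
    state = _CircuitState(condition, config, priors)
    n = condition.n_alternatives
    correct = condition.correct_channel or int(rng.integers(1, n + 1))

    rows = [state.pre_evidence_row()]
    outcome = decide(state.posterior, theta, rng)
    while not outcome.decided:
        if state.posterior.t >= step_cap:
            raise NonTerminationError(
                f"no decision after {step_cap} steps (circuit run, "
                f"N={n}, coherence={condition.coherence})"
            )
        obs = _next_obs(evidence, state.posterior.t, condition, correct, rng)
        rows.append(state.step(obs))
        outcome = decide(state.posterior, theta, rng)
    decision = outcome
    for _ in range(config.post_decision_steps):
        obs = _next_obs(evidence, state.posterior.t, condition, correct, rng)
        rows.append(state.step(obs))

    traces = _rows_to_traces(rows, state, decision, correct)
    # h(t) can depend on cortical values one latency ahead of t, so the
    # recorded rows hold NaN there; recompute from the completed histories
    # (the trailing rows may genuinely need unseen evidence and stay NaN).
    traces.h = np.array([state.h_at(r["t"]) for r in rows], dtype=float)
    return decision, traces


def run_msprt_trial_with_traces(
    condition: Condition,
    theta: float,
    config: CircuitConfig | None = None,
    rng: np.random.Generator | None = None,
    priors: np.ndarray | None = None,
    step_cap: int = DEFAULT_STEP_CAP,
    evidence: np.ndarray | None = None,
) -> tuple[DecisionOutcome, CircuitTraces]:
    """Trace runner for the non-recursive test (fixed priors, full history).

    The cortical trace is the cumulative simplified log-likelihood plus the
    constant baseline and the (never-updated) log-prior; with no delayed
    feedback there is no slope change locked to ``Delta``.
    """
    from scipy.special import logsumexp

    config = config or CircuitConfig()
    rng = rng if rng is not None else np.random.default_rng()
    n = condition.n_alternatives
    pr = np.full(n, 1.0 / n) if priors is None else np.asarray(priors, float)
    log_prior = np.log(pr)
    pref, null = condition.shapes()
    coeffs = likelihood_coefficients(pref, null)
    correct = condition.correct_channel or int(rng.integers(1, n + 1))
    lat = config.latencies

    s1 = np.zeros(n)
    s2 = np.zeros(n)
    neglog_hist = {0: -log_prior}
    rows = [
        {
            "t": 0,
            "cortex": np.full(n, config.l) + log_prior,
            "striatum": np.full(n, config.l) + log_prior,
            "bg_output": -log_prior,
            "thalamus": log_prior.copy(),
            "c": config.l,
            "h": 0.0,
        }
    ]
    t = 0
    decision = None
    while decision is None or t < decision.T + config.post_decision_steps:
        if t >= step_cap:
            raise NonTerminationError(f"no decision after {step_cap} steps")
        obs = _next_obs(evidence, t, condition, correct, rng)
        logx = np.log(obs)
        s1 += logx
        s2 += logx**2
        y = coeffs.g1 * s2 + coeffs.g2 * s1
        v = y + config.l + log_prior
        neglog = -v + logsumexp(v)
        t += 1
        neglog_hist[t] = neglog
        p_idx = max(0, t - lat.delta_bu)
        rows.append(
            {
                "t": t,
                "cortex": y + config.l + log_prior,
                "striatum": y + config.l + log_prior,
                "bg_output": neglog,
                "thalamus": -neglog_hist[p_idx],
                "c": config.l,
                "h": 0.0,
            }
        )
        if decision is None and neglog.min() <= theta:
            ties = np.flatnonzero(neglog == neglog.min())
            idx = ties[0] if ties.size == 1 else rng.choice(ties)
            decision = DecisionOutcome(status="decided", choice=int(idx) + 1, T=t)
    traces = _rows_to_traces(rows, None, decision, correct)
    return decision, traces


def _next_obs(evidence, t, condition, correct, rng):
    if evidence is not None:
        if t >= evidence.shape[1]:
            raise NonTerminationError("supplied evidence exhausted")
        return np.asarray(evidence[:, t], dtype=float)
    return _draw_step(condition, correct, rng)


def _rows_to_traces(rows, state, decision, correct) -> CircuitTraces:
    steps = np.array([r["t"] - 1 for r in rows])
    stack = {name: np.array([r[name] for r in rows]) for name in REGIONS}
    return CircuitTraces(
        steps=steps,
        cortex=stack["cortex"],
        striatum=stack["striatum"],
        bg_output=stack["bg_output"],
        thalamus=stack["thalamus"],
        c=np.array([r["c"] for r in rows], dtype=float),
        h=np.array([r["h"] for r in rows], dtype=float),
        choice=decision.choice,
        correct_channel=correct,
        T=decision.T,
    )


def baseline_bg_output(priors: np.ndarray) -> np.ndarray:
    """Pre-evidence basal-ganglia output: elementwise ``-log`` of the priors.

    A zero prior yields an infinite output and is flagged with a warning.
    """
    priors = np.asarray(priors, dtype=float)
    if abs(priors.sum() - 1.0) > 1e-10 or np.any(priors < 0):
        raise ValueError("priors must be nonnegative and sum to 1")
    if np.any(priors == 0.0):
        warnings.warn(
            "zero prior produces an infinite baseline output", RuntimeWarning
        )
    with np.errstate(divide="ignore"):
        return -np.log(priors)


@dataclass
class AveragedTraces:
    """Trial-averaged selected / non-selected traces for one alignment."""

    alignment: str
    steps: np.ndarray  # display steps (initiation) or steps relative to termination
    selected: dict  # region -> mean trace array
    non_selected: dict
    n_valid: np.ndarray  # trials contributing per step


def align_and_average_traces(
    traces: list[CircuitTraces],
    alignment: str = "initiation",
    extra_steps: int = 3,
) -> AveragedTraces:
    """Average traces across trials, split into selected / non-selected classes.

    Per trial, the *selected* trace is the chosen hypothesis' column and the
    *non-selected* one the mean over the remaining columns.  The average at
    each aligned step runs over the trials still valid there, truncated at
    the median termination plus ``extra_steps`` steps.  ``"termination"``
    alignment indexes backwards from each trial's threshold crossing.
    """
    if not traces:
        raise ValueError("need at least one trace")
    if alignment not in ("initiation", "termination"):
        raise ValueError("alignment must be 'initiation' or 'termination'")
    med_T = float(np.median([tr.T for tr in traces]))
    if alignment == "initiation":
        # display steps -1 .. median termination step + extra
        last = int(math.floor(med_T - 1 + extra_steps))
        steps = np.arange(-1, last + 1)
        index_of = lambda tr, s: s + 1  # row index of display step s
    else:
        first = -int(math.ceil(med_T)) - 1
        post = min(tr.steps[-1] - (tr.T - 1) for tr in traces)
        steps = np.arange(first, post + 1)
        index_of = lambda tr, s: tr.termination_index + s

    sel = {name: np.full(steps.size, np.nan) for name in REGIONS}
    non = {name: np.full(steps.size, np.nan) for name in REGIONS}
    n_valid = np.zeros(steps.size, dtype=int)
    for k, s in enumerate(steps):
        acc_sel = {name: [] for name in REGIONS}
        acc_non = {name: [] for name in REGIONS}
        for tr in traces:
            idx = index_of(tr, s)
            if not 0 <= idx < tr.steps.size:
                continue
            chosen = tr.choice - 1
            others = [i for i in range(tr.cortex.shape[1]) if i != chosen]
            for name in REGIONS:
                arr = tr.region(name)
                acc_sel[name].append(arr[idx, chosen])
                acc_non[name].append(arr[idx, others].mean())
        n_valid[k] = len(acc_sel["cortex"])
        if n_valid[k]:
            for name in REGIONS:
                sel[name][k] = float(np.mean(acc_sel[name]))
                non[name][k] = float(np.mean(acc_non[name]))
    return AveragedTraces(
        alignment=alignment, steps=steps, selected=sel, non_selected=non, n_valid=n_valid
    )
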