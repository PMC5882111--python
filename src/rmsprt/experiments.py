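"""Monte Carlo drivers over the task grid (N x coherence), with aggregation.

An experiment grid calibrates one decision threshold per condition against
the behavioural error-rate targets, simulates a fixed total number of
trials split equally across the coherence levels, and aggregates decision
sample sizes into decision and reaction times per outcome.  Trace
experiments do the same trial-by-trial on the circuit mapping and return
trial-averaged, initiation- and termination-aligned region traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behaviour import DEFAULT_NON_DECISION_MS
from .circuit import CircuitConfig, align_and_average_traces, run_trial_with_traces
from .evidence import Condition, error_rate_target
from .inference import DecisionEvaluator, calibrate_threshold
from .parameters import COHERENCES, ParameterSet, default_registry

__all__ = [
    "ExperimentPlan",
    "run_experiment_grid",
    "rt_histograms",
    "trace_experiment",
    "calibrate_grid",
]

#: Default per-experiment totals, split equally across the 5 coherences.
DEFAULT_TOTAL_TRIALS = {2: 3200, 4: 4800}


@dataclass(frozen=True)
class ExperimentPlan:
    """Specification of a simulated behavioural experiment."""

    parameter_sets: dict[int, str] = field(
        default_factory=lambda: {2: "omega_d_n2", 4: "omega_d_n4"}
    )
    n_list: tuple[int, ...] = (2, 4)
    coherences: tuple[str, ...] = COHERENCES
    total_trials: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_TOTAL_TRIALS)
    )
    n_experiments: int = 1
    seed: int = 0
    non_decision_ms: float = DEFAULT_NON_DECISION_MS
    scaling_n: float = 40.0
    calibration_trials: int = 10_000
    registry: dict[str, ParameterSet] | None = field(default=None, repr=False)

    def trials_per_condition(self, n_alternatives: int) -> int:
        total = self.total_trials[n_alternatives]
        per, rem = divmod(total, len(self.coherences))
        if rem:
            raise ValueError(
                f"total trials {total} not divisible by "
                f"{len(self.coherences)} coherences"
            )
        return per

    def condition(self, n_alternatives: int, coherence: str) -> Condition:
        return Condition(
            n_alternatives,
            coherence,
            self.parameter_sets[n_alternatives],
            self.scaling_n,
            registry=self.registry,
        )


def calibrate_grid(plan: ExperimentPlan) -> dict[tuple[int, str], float]:
    """Calibrated threshold per (N, coherence) cell of the plan."""
    ss = np.random.SeedSequence([plan.seed, 0x5EED])
    thetas: dict[tuple[int, str], float] = {}
    for n_alt in plan.n_list:
        for coh in plan.coherences:
            rng = np.random.default_rng(ss.spawn(1)[0])
            cond = plan.condition(n_alt, coh)
            eps = error_rate_target(float(coh), n_alt)
            thetas[(n_alt, coh)] = calibrate_threshold(
                cond, eps, plan.calibration_trials, rng
            )
    return thetas


def run_experiment_grid(
    plan: ExperimentPlan,
    thetas: dict[tuple[int, str], float] | None = None,
    return_trials: bool = False,
):
    """Simulate the plan; returns per-experiment, per-condition summaries.

    The summary frame has one row per (experiment, N, coherence, outcome)
    with mean decision sample size, decision time, reaction time and the
    achieved error rate; all reproducible from ``plan.seed``.  With
    ``return_trials`` the trial-level table (choice, correctness, T,
    reaction time) is returned as well.
    """
    if thetas is None:
        thetas = calibrate_grid(plan)
    registry = plan.registry if plan.registry is not None else default_registry()
    ss = np.random.SeedSequence([plan.seed, 0x7A1A])
    summary_rows = []
    trial_rows = []
    for exp in range(plan.n_experiments):
        for n_alt in plan.n_list:
            per_coh = plan.trials_per_condition(n_alt)
            label = plan.parameter_sets[n_alt]
            for coh in plan.coherences:
                rng = np.random.default_rng(ss.spawn(1)[0])
                cond = plan.condition(n_alt, coh)
                pair = registry[label].get(coh)
                ev = DecisionEvaluator(cond, per_coh, rng)
                T, choice, correct = ev.decision_stats(thetas[(n_alt, coh)])
                err = 1.0 - float(correct.mean())
                mu = {"correct": pair.preferred.mean_isi, "error": pair.null.mean_isi}
                for outcome, mask in (("correct", correct), ("error", ~correct)):
                    if not mask.any():
                        continue
                    mean_T = float(T[mask].mean())
                    tau = (mean_T + 0.5) * mu[outcome]
                    summary_rows.append(
                        {
                            "experiment": exp,
                            "n_alternatives": n_alt,
                            "coherence": float(coh),
                            "parameter_set": label,
                            "outcome": outcome,
                            "n_trials": int(mask.sum()),
                            "mean_T": mean_T,
                            "mean_decision_time_ms": tau,
                            "mean_reaction_time_ms": tau + plan.non_decision_ms,
                            "error_rate": err,
                            "theta": thetas[(n_alt, coh)],
                        }
                    )
                if return_trials:
                    rt = (T + 0.5) * np.where(
                        correct, pair.preferred.mean_isi, pair.null.mean_isi
                    ) + plan.non_decision_ms
                    trial_rows.append(
                        pd.DataFrame(
                            {
                                "experiment": exp,
                                "n_alternatives": n_alt,
                                "coherence": float(coh),
                                "parameter_set": label,
                                "choice": choice,
                                "correct": correct,
                                "T": T,
                                "reaction_time_ms": rt,
                            }
                        )
                    )
    summary = pd.DataFrame(summary_rows)
    if return_trials:
        trials = pd.concat(trial_rows, ignore_index=True)
        trials.insert(0, "trial_id", np.arange(len(trials)))
        return summary, trials
    return summary


def rt_histograms(trials: pd.DataFrame, bin_width: float = 50.0):
    """Reaction-time histograms and skewness per (N, coherence, outcome).

    Returns ``(histograms, skewness)``: binned counts with left edges, and
    the sample skewness of each condition/outcome cell (positive skew means
    a long right tail).
    """
    if trials.empty:
        raise ValueError("no trials to histogram")
    hist_rows = []
    skew_rows = []
    keys = ["n_alternatives", "coherence"]
    for (n_alt, coh), grp in trials.groupby(keys):
        for outcome, mask in (("correct", grp["correct"]), ("error", ~grp["correct"])):
            rts = grp.loc[mask, "reaction_time_ms"].to_numpy()
            if rts.size == 0:
                continue
            lo = np.floor(rts.min() / bin_width) * bin_width
            hi = np.ceil(rts.max() / bin_width) * bin_width
            edges = np.arange(lo, hi + bin_width, bin_width)
            if edges.size < 2:
                edges = np.array([lo, lo + bin_width])
            counts, edges = np.histogram(rts, bins=edges)
            for left, cnt in zip(edges[:-1], counts):
                hist_rows.append(
                    {
                        "n_alternatives": n_alt,
                        "coherence": coh,
                        "outcome": outcome,
                        "bin_left_ms": left,
                        "bin_width_ms": bin_width,
                        "count": int(cnt),
                    }
                )
            skew_rows.append(
                {
                    "n_alternatives": n_alt,
                    "coherence": coh,
                    "outcome": outcome,
                    "n_trials": int(rts.size),
                    "skewness": (
                        float(stats.skew(rts))
                        if rts.size > 2 and rts.std() > 0
                        else np.nan
                    ),
                    "q95_ms": float(np.quantile(rts, 0.95)),
                }
            )
    return pd.DataFrame(hist_rows), pd.DataFrame(skew_rows)


def trace_experiment(
    plan: ExperimentPlan,
    config: CircuitConfig | None = None,
    thetas: dict[tuple[int, str], float] | None = None,
    correct_only: bool = True,
):
    """Run circuit-mapped trials and average traces per condition.

    Returns a dict keyed ``(N, coherence)`` with the initiation- and
    termination-aligned :class:`~rmsprt.circuit.AveragedTraces` (selected vs
    non-selected hypothesis classes) and the underlying outcomes.
    """
    config = config or CircuitConfig()
    if thetas is None:
        thetas = calibrate_grid(plan)
    ss = np.random.SeedSequence([plan.seed, 0x7ACE])
    out = {}
    for n_alt in plan.n_list:
        per_coh = plan.trials_per_condition(n_alt)
        for coh in plan.coherences:
            cond = plan.condition(n_alt, coh)
            theta = thetas[(n_alt, coh)]
            rng = np.random.default_rng(ss.spawn(1)[0])
            traces = []
            outcomes = []
            for _ in range(per_coh):
                outcome, tr = run_trial_with_traces(cond, theta, config, rng)
                outcomes.append(outcome)
                if correct_only and tr.choice != tr.correct_channel:
                    continue
                traces.append(tr)
            out[(n_alt, coh)] = {
                "initiation": align_and_average_traces(traces, "initiation"),
                "termination": align_and_average_traces(traces, "termination"),
                "outcomes": outcomes,
                "theta": theta,
            }
    return out
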