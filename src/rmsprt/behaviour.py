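"""Reaction-time conversion and the information-loss / depletion pipeline.

The discrete-time test consumes ``T`` vector observations before deciding.
Because the mean number of ISIs in the fastest channel of an equivalent
continuous-time, spike-based test matches the discrete observation count,
``T`` converts to a mean decision time in milliseconds as

    tau_c = (<T>_c + 0.5) * mu_pref_n     (correct trials)
    tau_e = (<T>_e + 0.5) * mu_null_n     (error trials)

where the 0.5 is the expected fraction of an ISI from decision initiation
to the first spike, and ``mu_* n`` are the unscaled registry mean ISIs of
the channel driving the selected hypothesis.  Reaction time adds a constant
non-decision time (sensory and motor latency; 200-300 ms plausible for
macaques, 250 ms default).

The sequential-test identity ``<T>_c >= I(eps, N) / K`` links mean decision
sample size to the discrimination information per observation ``K`` (bits
per ISI) and the total information ``I`` needed at error rate ``eps``.
Estimating ``I`` as ``I_hat = <T>_c * K`` from a full-information model run
and reading the subject's decision sample size off its reaction times
yields the discrimination information the subject effectively used,
``K_hat_m = I_hat / <T_hat>_c^m``, and hence the fraction of available
information it lost.  *Information depletion* then manufactures evidence
distributions carrying exactly ``K_hat_m``: the null-channel mean and SD
are moved towards the preferred ones by a common proportion until the pair's
divergence equals the target.  Because ``I_hat`` over-estimates the bound
(threshold overshoot), an *enhanced-match* correction rescales ``K_hat_m``
by the model-to-subject decision-time ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evidence import Condition, error_rate_target
from .inference import DecisionEvaluator, calibrate_threshold
from .parameters import (
    ChannelPair,
    IsiStatistics,
    ParameterSet,
    default_registry,
    kl_divergence_bits,
    lognormal_shape,
)

__all__ = [
    "BehaviourSummary",
    "InformationAccount",
    "mean_decision_time_correct",
    "mean_decision_time_error",
    "monkey_decision_samples",
    "information_account",
    "deplete_information",
    "enhanced_loss_correction",
    "chebyshev_interval",
    "InformationLossModel",
    "InformationLossResults",
]

DEFAULT_NON_DECISION_MS = 250.0


@dataclass(frozen=True)
class BehaviourSummary:
    """Per-condition, per-outcome behavioural aggregates of a simulation."""

    n_alternatives: int
    coherence: float
    parameter_set: str
    outcome: str  # "correct" or "error"
    n_trials: int
    mean_T: float
    mean_decision_time_ms: float
    mean_reaction_time_ms: float
    error_rate: float
    non_decision_time_ms: float = DEFAULT_NON_DECISION_MS


@dataclass(frozen=True)
class InformationAccount:
    """Information bookkeeping for one condition."""

    K: float  # bits/ISI available in the evidence
    I_hat: float  # estimated total information needed (bits)
    T_hat_monkey: float  # subject decision sample size (steps)
    K_hat_monkey: float  # bits/ISI the subject effectively used
    loss_percent: float


def mean_decision_time_correct(mean_T: float, pref_mean_isi: float) -> float:
    """Mean correct-trial decision time (ms) from the mean decision sample size."""
    if mean_T < 0:
        raise ValueError("mean_T must be >= 0")
    return (mean_T + 0.5) * pref_mean_isi


def mean_decision_time_error(mean_T: float, null_mean_isi: float) -> float:
    """Mean error-trial decision time (ms); error choices ride the null channel."""
    if mean_T < 0:
        raise ValueError("mean_T must be >= 0")
    return (mean_T + 0.5) * null_mean_isi


def monkey_decision_samples(
    mean_rt: float, non_decision_time: float, pref_mean_isi: float
) -> float:
    """Invert the correct-trial time conversion: reaction time -> decision samples."""
    decision_time = mean_rt - non_decision_time
    if decision_time <= 0:
        raise ValueError(
            f"non-positive decision time: mean_rt={mean_rt} ms with "
            f"non_decision_time={non_decision_time} ms"
        )
    return decision_time / pref_mean_isi - 0.5


def information_account(
    model_mean_T: float, K: float, monkey_T_hat: float
) -> InformationAccount:
    """Estimate the subject's per-ISI information and percentage loss."""
    if monkey_T_hat <= 0:
        raise ValueError("monkey_T_hat must be positive")
    if model_mean_T <= 0 or K <= 0:
        raise ValueError("model_mean_T and K must be positive")
    I_hat = model_mean_T * K
    K_hat = I_hat / monkey_T_hat
    return InformationAccount(
        K=K,
        I_hat=I_hat,
        T_hat_monkey=monkey_T_hat,
        K_hat_monkey=K_hat,
        loss_percent=(1.0 - K_hat / K) * 100.0,
    )


def deplete_information(
    pref: IsiStatistics,
    null: IsiStatistics,
    K_target: float,
    n: float = 1.0,
    tol_bits: float = 1e-9,
) -> IsiStatistics:
    """Shrink the preferred-null gap until the pair carries ``K_target`` bits.

    The new null statistics are ``pref + gamma * (null - pref)`` in both
    moments, with ``gamma`` in (0, 1] found by bisection so that the
    divergence from the preferred to the new null density equals
    ``K_target`` (to ``tol_bits``).
    """
    pref_shape = lognormal_shape(pref, n)
    K_avail = kl_divergence_bits(pref_shape, lognormal_shape(null, n))
    if K_target <= 0:
        raise ValueError("K_target must be positive")
    if K_target > K_avail + 1e-12:
        raise ValueError(
            f"K_target ({K_target:.6g} bits) exceeds the available "
            f"discrimination information ({K_avail:.6g} bits)"
        )

    def null_at(gamma: float) -> IsiStatistics:
        return IsiStatistics(
            mean_isi=pref.mean_isi + gamma * (null.mean_isi - pref.mean_isi),
            sd_isi=pref.sd_isi + gamma * (null.sd_isi - pref.sd_isi),
        )

    def kl_at(gamma: float) -> float:
        return kl_divergence_bits(pref_shape, lognormal_shape(null_at(gamma), n))

    if abs(K_target - K_avail) <= tol_bits:
        return null
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        k = kl_at(mid)
        if abs(k - K_target) <= tol_bits:
            return null_at(mid)
        if k < K_target:
            lo = mid
        else:
            hi = mid
    return null_at(0.5 * (lo + hi))


def enhanced_loss_correction(
    K_hat: float, model_decision_time: float, monkey_decision_time: float
) -> float:
    """Rescale the subject's information estimate by the decision-time ratio.

    ``I_hat`` over-estimates the information bound, so a model run on
    statistics carrying ``K_hat`` decides faster than the subject; the ratio
    of model to subject decision time corrects the over-estimate (loss grows).
    """
    if K_hat <= 0 or model_decision_time <= 0 or monkey_decision_time <= 0:
        raise ValueError("all inputs must be positive")
    return K_hat * model_decision_time / monkey_decision_time


def chebyshev_interval(samples: np.ndarray, level: float = 0.99) -> tuple[float, float]:
    """Chebyshev confidence interval for the mean: ``mean +/- k * SD / sqrt(n)``.

    With ``k = 1 / sqrt(1 - level)`` (k = 10 at the 99% level) applied to the
    standard error, Chebyshev's inequality guarantees at least ``level``
    coverage of the true mean for any distribution with finite variance —
    a deliberately conservative interval.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    k = 1.0 / math.sqrt(1.0 - level)
    half = k * x.std(ddof=1) / math.sqrt(x.size)
    m = float(x.mean())
    return m - half, m + half


# ---------------------------------------------------------------------------
# Information-loss estimation as a fitted model
# ---------------------------------------------------------------------------


class InformationLossModel:
    """Estimate the discrimination information a subject used, from reaction times.

    Parameters
    ----------
    behaviour_table
        DataFrame with columns ``n_alternatives``, ``coherence``,
        ``mean_rt_ms`` — per-condition mean reaction times of correct
        trials (e.g. monkey behaviour, or the packaged synthetic fixture).
    registry
        Parameter-set registry providing the full-information (``omega``)
        statistics; defaults to the packaged MT registry.
    non_decision_ms
        Constant sensory/motor latency subtracted from reaction times.
    scaling_n
        Data scaling factor used for model simulations (inference-invariant).

    ``fit`` simulates the full-information model per condition to estimate
    ``I_hat``, inverts the subject's reaction times into decision sample
    sizes, forms ``K_hat_m`` and the percentage loss, optionally applies
    enhanced-match refinements, and depletes the null statistics to carry
    exactly ``K_hat_m``.
    """

    REQUIRED_COLUMNS = ("n_alternatives", "coherence", "mean_rt_ms")

    def __init__(
        self,
        behaviour_table: pd.DataFrame,
        registry: dict[str, ParameterSet] | None = None,
        non_decision_ms: float = DEFAULT_NON_DECISION_MS,
        scaling_n: float = 40.0,
    ) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in behaviour_table.columns]
        if missing:
            raise ValueError(f"behaviour table missing columns: {missing}")
        self.table = behaviour_table.reset_index(drop=True)
        self.registry = registry if registry is not None else default_registry()
        self.non_decision_ms = float(non_decision_ms)
        self.scaling_n = float(scaling_n)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "InformationLossModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(
        self,
        trials_per_condition: int = 10_000,
        refine: int = 5,
        seed: int = 0,
        calibration_trials: int = 10_000,
        refine_rtol: float = 0.005,
        calibration_tol: float | None = None,
    ) -> "InformationLossResults":
        """Run the estimation pipeline; returns an :class:`InformationLossResults`.

        ``refine`` caps the enhanced-match fixed-point iterations (rescaling
        the information estimate by the model-to-subject decision-time
        ratio); iteration stops early once the ratio is within
        ``refine_rtol`` of 1.
        """
        ss = np.random.SeedSequence(seed)
        rows = []
        for idx, rec in self.table.iterrows():
            n_alt = int(rec["n_alternatives"])
            coh = float(rec["coherence"])
            rt = float(rec["mean_rt_ms"])
            child = np.random.default_rng(ss.spawn(1)[0])
            rows.append(
                self._fit_condition(
                    n_alt, coh, rt, trials_per_condition, refine,
                    calibration_trials, child, refine_rtol, calibration_tol,
                )
            )
        frame = pd.DataFrame(rows)
        return InformationLossResults(model=self, frame=frame)

    def _fit_condition(
        self,
        n_alt: int,
        coherence: float,
        mean_rt: float,
        trials: int,
        refine: int,
        calibration_trials: int,
        rng: np.random.Generator,
        refine_rtol: float = 0.005,
        calibration_tol: float | None = None,
    ) -> dict:
        pair = self.registry["omega"].get(coherence)
        pref_shape = lognormal_shape(pair.preferred, self.scaling_n)
        null_shape = lognormal_shape(pair.null, self.scaling_n)
        K = kl_divergence_bits(pref_shape, null_shape)
        eps = error_rate_target(coherence, n_alt)
        cond = Condition(
            n_alt, coherence, "omega", self.scaling_n, registry=self.registry
        )
        mean_T_model, _ = self._simulate_mean_T(
            cond, eps, trials, calibration_trials, rng, calibration_tol
        )
        T_hat = monkey_decision_samples(
            mean_rt, self.non_decision_ms, pair.preferred.mean_isi
        )
        account = information_account(mean_T_model, K, T_hat)
        K_hat = account.K_hat_monkey
        monkey_decision_ms = mean_rt - self.non_decision_ms
        # an estimate slightly above the available information is Monte
        # Carlo noise (clamped; refinement pulls it back down), but far
        # above it the behaviour is incompatible with this registry
        self._check_feasible(K_hat, K, n_alt, coherence)
        model_decision_ms = math.nan
        for _ in range(refine):
            mean_T_d = self._simulate_depleted(
                pair, n_alt, coherence, K_hat, eps, trials,
                calibration_trials, rng, calibration_tol,
            )
            model_decision_ms = mean_decision_time_correct(
                mean_T_d, pair.preferred.mean_isi
            )
            ratio = model_decision_ms / monkey_decision_ms
            K_hat = enhanced_loss_correction(
                K_hat, model_decision_ms, monkey_decision_ms
            )
            self._check_feasible(K_hat, K, n_alt, coherence)
            if abs(ratio - 1.0) < refine_rtol:
                break
        depleted_null = deplete_information(
            pair.preferred, pair.null, min(K_hat, K), self.scaling_n
        )
        # model RT reported from the last refinement run (within refine_rtol
        # of the final estimate's RT); with refine=0 no depleted run exists
        model_rt = (
            model_decision_ms + self.non_decision_ms
            if not math.isnan(model_decision_ms)
            else math.nan
        )
        return {
            "n_alternatives": n_alt,
            "coherence": coherence,
            "K_bits": K,
            "mean_T_model": mean_T_model,
            "I_hat_bits": account.I_hat,
            "T_hat_monkey": T_hat,
            "K_hat_monkey": K_hat,
            "loss_percent": (1.0 - K_hat / K) * 100.0,
            "depleted_null_mean": depleted_null.mean_isi,
            "depleted_null_sd": depleted_null.sd_isi,
            "monkey_mean_rt_ms": mean_rt,
            "model_mean_rt_ms": model_rt,
        }

    @staticmethod
    def _check_feasible(
        K_hat: float, K_avail: float, n_alt: int, coherence: float,
        margin: float = 1.15,
    ) -> None:
        if K_hat > margin * K_avail:
            raise ValueError(
                f"N={n_alt}, {coherence}%: behaviour implies "
                f"{K_hat:.4g} bits/ISI but the registry carries only "
                f"{K_avail:.4g}; reaction times are too fast for this "
                "evidence (infeasible depletion target)"
            )

    def _simulate_mean_T(
        self,
        cond: Condition,
        eps: float,
        trials: int,
        calibration_trials: int,
        rng: np.random.Generator,
        calibration_tol: float | None = None,
    ) -> tuple[float, float]:
        theta = calibrate_threshold(
            cond, eps, calibration_trials, rng, tol=calibration_tol
        )
        ev = DecisionEvaluator(cond, trials, rng)
        T, _, correct = ev.decision_stats(theta)
        if not correct.any():
            raise RuntimeError("no correct trials; cannot estimate mean T")
        return float(T[correct].mean()), 1.0 - float(correct.mean())

    def _simulate_depleted(
        self,
        pair: ChannelPair,
        n_alt: int,
        coherence: float,
        K_target: float,
        eps: float,
        trials: int,
        calibration_trials: int,
        rng: np.random.Generator,
        calibration_tol: float | None = None,
    ) -> float:
        K_avail = kl_divergence_bits(
            lognormal_shape(pair.preferred, self.scaling_n),
            lognormal_shape(pair.null, self.scaling_n),
        )
        null_d = deplete_information(
            pair.preferred, pair.null, min(K_target, K_avail), self.scaling_n
        )
        pset = ParameterSet(
            label="depleted",
            entries={
                key: ChannelPair(preferred=pair.preferred, null=null_d)
                for key in [f"{coherence:g}"]
            },
            neuron_count={},
        )
        cond = Condition(
            n_alt, coherence, "depleted", self.scaling_n, registry={"depleted": pset}
        )
        mean_T, _ = self._simulate_mean_T(
            cond, eps, trials, calibration_trials, rng, calibration_tol
        )
        return mean_T


class InformationLossResults:
    """Results of :meth:`InformationLossModel.fit`.

    ``frame`` holds one row per condition with the information account
    (``K_bits``, ``I_hat_bits``, ``T_hat_monkey``, ``K_hat_monkey``,
    ``loss_percent``) and the depleted null-channel statistics.
    """

    def __init__(self, model: InformationLossModel, frame: pd.DataFrame) -> None:
        self.model = model
        self.frame = frame

    @property
    def loss_percent(self) -> pd.Series:
        return self.frame.set_index(["n_alternatives", "coherence"])["loss_percent"]

    def account(self, n_alternatives: int, coherence: float) -> InformationAccount:
        sel = self.frame[
            (self.frame["n_alternatives"] == n_alternatives)
            & (self.frame["coherence"] == float(coherence))
        ]
        if sel.empty:
            raise KeyError(f"no fitted condition N={n_alternatives}, {coherence}%")
        r = sel.iloc[0]
        return InformationAccount(
            K=r["K_bits"],
            I_hat=r["I_hat_bits"],
            T_hat_monkey=r["T_hat_monkey"],
            K_hat_monkey=r["K_hat_monkey"],
            loss_percent=r["loss_percent"],
        )

    def depleted_pairs(self) -> dict[tuple[int, str], ChannelPair]:
        """(N, coherence-key) -> depleted channel statistics."""
        out = {}
        for _, r in self.frame.iterrows():
            pair = self.model.registry["omega"].get(r["coherence"])
            out[(int(r["n_alternatives"]), f"{r['coherence']:g}")] = ChannelPair(
                preferred=pair.preferred,
                null=IsiStatistics(r["depleted_null_mean"], r["depleted_null_sd"]),
            )
        return out

    def to_parameter_table(self, path: str | Path) -> pd.DataFrame:
        """Write a registry-format CSV with the fitted depleted sets.

        Requires the fit to cover all registry coherences for both N = 2
        and N = 4; the result reloads with
        :func:`rmsprt.parameters.load_parameter_table`.
        """
        omega = self.model.registry["omega"]
        pairs = self.depleted_pairs()
        rows = []
        for coh in omega.coherences:
            entry = omega.get(coh)
            row = {
                "coherence": coh,
                "n_neurons": omega.neuron_count.get(coh, 0),
                "pref_mean": entry.preferred.mean_isi,
                "pref_sd": entry.preferred.sd_isi,
                "omega_null_mean": entry.null.mean_isi,
                "omega_null_sd": entry.null.sd_isi,
            }
            for n_alt, prefix in ((2, "omegad_n2"), (4, "omegad_n4")):
                key = (n_alt, coh)
                if key not in pairs:
                    raise ValueError(
                        f"fit does not cover N={n_alt} at {coh}% coherence; "
                        "cannot write a complete registry"
                    )
                row[f"{prefix}_null_mean"] = round(pairs[key].null.mean_isi, 6)
                row[f"{prefix}_null_sd"] = round(pairs[key].null.sd_isi, 6)
            rows.append(row)
        frame = pd.DataFrame(rows)
        frame.to_csv(path, index=False)
        return frame

    def summary(self) -> str:
        """Plain-text summary table of the information account per condition."""
        cols = [
            "n_alternatives",
            "coherence",
            "K_bits",
            "I_hat_bits",
            "T_hat_monkey",
            "K_hat_monkey",
            "loss_percent",
            "monkey_mean_rt_ms",
            "model_mean_rt_ms",
        ]
        body = self.frame[cols].to_string(
            index=False, float_format=lambda v: f"{v:9.3f}"
        )
        head = (
            "Information-loss estimation\n"
            f"  non-decision time: {self.model.non_decision_ms:.0f} ms; "
            f"data scaling n = {self.model.scaling_n:g}\n"
        )
        return head + body

    def plot(self, ax=None):
        """Available vs used discrimination information across coherence."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for n_alt, grp in self.frame.groupby("n_alternatives"):
            grp = grp.sort_values("coherence")
            ax.plot(grp["coherence"], grp["K_hat_monkey"], "o-", label=f"used, N={n_alt}")
        omega_rows = self.frame.drop_duplicates("coherence").sort_values("coherence")
        ax.plot(omega_rows["coherence"], omega_rows["K_bits"], "k--", label="available")
        ax.set_xlabel("coherence (%)")
        ax.set_ylabel("discrimination information (bits/ISI)")
        ax.legend()
        return ax
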