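"""Synthetic behavioural fixture: stand-in for unavailable subject reaction times.

The information-loss pipeline needs per-condition mean reaction times of a
real subject, which this repository cannot ship.  The fixture generator
produces a synthetic table by running the decision model itself on a
*secretly* information-depleted registry plus a constant non-decision time,
and records the secret (per-condition depleted statistics and their
divergences) so that parameter-recovery tests can verify the estimation
pipeline end to end: feeding the fixture reaction times and the
full-information registry into :class:`~rmsprt.behaviour.InformationLossModel`
should recover the secret per-condition discrimination information.

The secret per-coherence loss fractions are fixed study conditions chosen
to emulate the qualitative pattern of primate behaviour (loss grows with
coherence); by construction the fixture reaction times exceed the
full-information model's upper-bound reaction times in every condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behaviour import DEFAULT_NON_DECISION_MS, deplete_information
from .evidence import Condition, error_rate_target
from .inference import DecisionEvaluator, calibrate_threshold
from .parameters import (
    COHERENCES,
    ChannelPair,
    ParameterSet,
    default_registry,
    kl_divergence_bits,
    lognormal_shape,
)

__all__ = [
    "SECRET_LOSS_FRACTIONS",
    "PACKAGED_FIXTURE_SEED",
    "FixtureResult",
    "generate_fixture",
    "load_packaged_fixture",
]

#: Seed (and default sizes) used to generate the packaged fixture CSV.
PACKAGED_FIXTURE_SEED = 7

#: Fraction of the available discrimination information removed per
#: coherence level when generating the synthetic subject (both N).
SECRET_LOSS_FRACTIONS = {
    "3.2": 0.20,
    "6.4": 0.35,
    "12.8": 0.50,
    "25.6": 0.65,
    "51.2": 0.80,
}


@dataclass
class FixtureResult:
    """Synthetic behaviour table plus the secret that generated it."""

    table: pd.DataFrame  # n_alternatives, coherence, mean_rt_ms, n_trials
    secret_kl: dict  # (N, coherence-key) -> bits carried by the secret set
    secret_pairs: dict  # (N, coherence-key) -> depleted ChannelPair
    non_decision_ms: float
    scaling_n: float


def load_packaged_fixture() -> pd.DataFrame:
    """The shipped synthetic behaviour table.

    Produced by ``generate_fixture(seed=PACKAGED_FIXTURE_SEED)`` at 10^4
    trials per condition; regenerate with that call (or ``rmsprt fixture``)
    to recover the secret depleted statistics behind it.
    """
    from importlib import resources

    with resources.files("rmsprt.data").joinpath(
        "synthetic_monkey_rt.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def generate_fixture(
    seed: int,
    trials_per_condition: int = 10_000,
    n_list: tuple[int, ...] = (2, 4),
    loss_fractions: dict[str, float] | None = None,
    non_decision_ms: float = DEFAULT_NON_DECISION_MS,
    scaling_n: float = 40.0,
    calibration_trials: int = 10_000,
    calibration_tol: float | None = None,
) -> FixtureResult:
    """Simulate a synthetic subject on a secretly depleted registry.

    Per condition: deplete the full-information statistics by the secret
    loss fraction, calibrate the threshold to the behavioural error-rate
    target, simulate, and convert the mean correct-trial decision sample
    size to a mean reaction time.  Deterministic given ``seed``.
    """
    losses = loss_fractions if loss_fractions is not None else SECRET_LOSS_FRACTIONS
    registry = default_registry()
    omega = registry["omega"]
    ss = np.random.SeedSequence([seed, 0xF1C5])
    rows = []
    secret_kl = {}
    secret_pairs = {}
    for n_alt in n_list:
        for coh in COHERENCES:
            pair = omega.get(coh)
            K = kl_divergence_bits(
                lognormal_shape(pair.preferred, scaling_n),
                lognormal_shape(pair.null, scaling_n),
            )
            K_secret = (1.0 - losses[coh]) * K
            null_d = deplete_information(pair.preferred, pair.null, K_secret, scaling_n)
            secret = ChannelPair(preferred=pair.preferred, null=null_d)
            pset = ParameterSet(
                label="secret", entries={coh: secret}, neuron_count={}
            )
            cond = Condition(
                n_alt, coh, "secret", scaling_n, registry={"secret": pset}
            )
            rng = np.random.default_rng(ss.spawn(1)[0])
            eps = error_rate_target(float(coh), n_alt)
            theta = calibrate_threshold(
                cond, eps, calibration_trials, rng, tol=calibration_tol
            )
            ev = DecisionEvaluator(cond, trials_per_condition, rng)
            T, _, correct = ev.decision_stats(theta)
            mean_T = float(T[correct].mean())
            rt = (mean_T + 0.5) * pair.preferred.mean_isi + non_decision_ms
            rows.append(
                {
                    "n_alternatives": n_alt,
                    "coherence": float(coh),
                    "mean_rt_ms": rt,
                    "n_trials": int(correct.sum()),
                }
            )
            secret_kl[(n_alt, coh)] = K_secret
            secret_pairs[(n_alt, coh)] = secret
    return FixtureResult(
        table=pd.DataFrame(rows),
        secret_kl=secret_kl,
        secret_pairs=secret_pairs,
        non_decision_ms=non_decision_ms,
        scaling_n=scaling_n,
    )
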