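"""Inter-spike-interval statistics registry and lognormal information measures.

The decision evidence in this package is a stream of inter-spike intervals
(ISIs) from motion-sensitive sensory neurons (area MT).  ISIs during the
random-dot-motion task are well described by lognormal distributions, so each
evidence channel is summarised by the mean and standard deviation of its ISI
(in ms) for the *preferred* motion direction (the neuron's tuned direction,
faster firing, shorter ISIs) and the opposite *null* direction.

Three parameter sets are packaged, indexed by motion coherence (%):

``omega``
    Statistics measured directly from MT populations.
``omega_d_n2`` / ``omega_d_n4``
    Information-depleted variants for 2- and 4-alternative tasks, in which
    the null distribution has been moved towards the preferred one so that
    the pair carries only the discrimination information estimated from
    monkey behaviour.

Discrimination information between the two channel distributions is the
Kullback-Leibler divergence from the preferred-direction ISI density to the
null one, in bits per ISI; for lognormals it has the closed form of the KL
divergence between the corresponding normal distributions of log-ISIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "IsiStatistics",
    "LognormalShape",
    "ChannelPair",
    "ParameterSet",
    "RegistryFormatError",
    "COHERENCES",
    "PARAMETER_SET_LABELS",
    "load_parameter_table",
    "default_registry",
    "lognormal_shape",
    "implied_statistics",
    "kl_divergence_bits",
]

#: Motion-coherence levels (%) present in the packaged registry.
COHERENCES = ("3.2", "6.4", "12.8", "25.6", "51.2")

PARAMETER_SET_LABELS = ("omega", "omega_d_n2", "omega_d_n4")

_TABLE_COLUMNS = [
    "coherence",
    "n_neurons",
    "pref_mean",
    "pref_sd",
    "omega_null_mean",
    "omega_null_sd",
    "omegad_n2_null_mean",
    "omegad_n2_null_sd",
    "omegad_n4_null_mean",
    "omegad_n4_null_sd",
]


class RegistryFormatError(ValueError):
    """Raised when a parameter table violates the registry format or invariants."""


@dataclass(frozen=True)
class IsiStatistics:
    """Mean and standard deviation of inter-spike intervals, in ms."""

    mean_isi: float
    sd_isi: float

    def __post_init__(self) -> None:
        if not (self.mean_isi > 0 and self.sd_isi > 0):
            raise RegistryFormatError(
                f"ISI statistics must be positive, got mean={self.mean_isi}, "
                f"sd={self.sd_isi}"
            )


@dataclass(frozen=True)
class LognormalShape:
    """Location/scale of a lognormal ISI density on the log-ms axis.

    ``kappa`` is the mean and ``theta2`` the variance of the log-ISI; a
    lognormal with these parameters has mean ``exp(kappa + theta2/2)`` and
    variance ``(exp(theta2) - 1) exp(2 kappa + theta2)``.
    """

    kappa: float
    theta2: float

    def __post_init__(self) -> None:
        if not self.theta2 > 0:
            raise ValueError(f"theta2 must be positive, got {self.theta2}")

    @property
    def theta(self) -> float:
        return math.sqrt(self.theta2)


@dataclass(frozen=True)
class ChannelPair:
    """Preferred- and null-direction ISI statistics for one coherence level."""

    preferred: IsiStatistics
    null: IsiStatistics


@dataclass(frozen=True)
class ParameterSet:
    """Coherence-indexed registry of preferred/null ISI statistics.

    Coherence keys are exact decimal strings (e.g. ``"25.6"``) to avoid
    float-key pitfalls; :meth:`get` accepts numbers and normalises them.
    """

    label: str
    entries: Mapping[str, ChannelPair]
    neuron_count: Mapping[str, int]

    def get(self, coherence: float | str) -> ChannelPair:
        key = _coherence_key(coherence)
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(
                f"coherence {coherence!r} not in registry "
                f"(available: {sorted(self.entries)})"
            ) from None

    @property
    def coherences(self) -> tuple[str, ...]:
        return tuple(self.entries)


def _coherence_key(coherence: float | str) -> str:
    if isinstance(coherence, str):
        return coherence
    # exact decimal rendering for the registry's one-decimal levels
    return f"{float(coherence):g}"


def _check_invariants(sets: dict[str, ParameterSet]) -> None:
    omega = sets["omega"]
    for label, pset in sets.items():
        if set(pset.entries) != set(COHERENCES):
            raise RegistryFormatError(
                f"{label}: coherence keys must be exactly {COHERENCES}, "
                f"got {tuple(pset.entries)}"
            )
        for coh, pair in pset.entries.items():
            if not pair.preferred.mean_isi < pair.null.mean_isi:
                raise RegistryFormatError(
                    f"{label} at {coh}%: preferred mean ISI "
                    f"({pair.preferred.mean_isi}) must be smaller than null "
                    f"({pair.null.mean_isi})"
                )
    for label in ("omega_d_n2", "omega_d_n4"):
        for coh in COHERENCES:
            lo = omega.get(coh).preferred.mean_isi
            hi = omega.get(coh).null.mean_isi
            mid = sets[label].get(coh).null.mean_isi
            if not (lo < mid < hi):
                raise RegistryFormatError(
                    f"{label} at {coh}%: depleted null mean {mid} must lie "
                    f"strictly between the preferred ({lo}) and undepleted "
                    f"null ({hi}) means"
                )


def load_parameter_table(source: str | Path | None = None) -> dict[str, ParameterSet]:
    """Load the ISI-statistics registry from delimited text.

    Parameters
    ----------
    source
        Path to a CSV with the ten registry columns; ``None`` loads the
        packaged MT table.

    Returns
    -------
    dict mapping label -> :class:`ParameterSet` for labels ``omega``,
    ``omega_d_n2`` and ``omega_d_n4``.  The depleted sets share their
    preferred-direction columns with ``omega``.
    """
    if source is None:
        with resources.files("rmsprt.data").joinpath("mt_isi_table.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(source)
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise RegistryFormatError(f"parameter table missing columns: {missing}")

    entries: dict[str, dict[str, ChannelPair]] = {lab: {} for lab in PARAMETER_SET_LABELS}
    counts: dict[str, int] = {}
    null_cols = {
        "omega": ("omega_null_mean", "omega_null_sd"),
        "omega_d_n2": ("omegad_n2_null_mean", "omegad_n2_null_sd"),
        "omega_d_n4": ("omegad_n4_null_mean", "omegad_n4_null_sd"),
    }
    for _, row in table.iterrows():
        key = _coherence_key(row["coherence"])
        try:
            pref = IsiStatistics(float(row["pref_mean"]), float(row["pref_sd"]))
            for label, (mcol, scol) in null_cols.items():
                null = IsiStatistics(float(row[mcol]), float(row[scol]))
                entries[label][key] = ChannelPair(preferred=pref, null=null)
        except (RegistryFormatError, ValueError) as exc:
            raise RegistryFormatError(f"row for coherence {key}%: {exc}") from exc
        counts[key] = int(row["n_neurons"])

    sets = {
        label: ParameterSet(label=label, entries=entries[label], neuron_count=counts)
        for label in PARAMETER_SET_LABELS
    }
    _check_invariants(sets)
    return sets


_DEFAULT_REGISTRY: dict[str, ParameterSet] | None = None


def default_registry() -> dict[str, ParameterSet]:
    """The packaged MT registry, loaded once and cached."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_parameter_table(None)
    return _DEFAULT_REGISTRY


def lognormal_shape(stats: IsiStatistics, n: float = 1.0) -> LognormalShape:
    """Lognormal shape parameters matching ``stats`` scaled by ``1/n``.

    The data scaling factor ``n`` divides both moments, so ``theta2`` (a
    coefficient of variation measure) is invariant to ``n`` while ``kappa``
    shifts by ``-log n``.
    """
    if not n > 0:
        raise ValueError(f"scaling factor n must be positive, got {n}")
    mu = stats.mean_isi / n
    sigma = stats.sd_isi / n
    theta2 = math.log(sigma**2 / mu**2 + 1.0)
    kappa = math.log(mu) - theta2 / 2.0
    return LognormalShape(kappa=kappa, theta2=theta2)


def implied_statistics(shape: LognormalShape) -> IsiStatistics:
    """Mean and SD of the lognormal with the given shape (closed-form back-conversion)."""
    mean = math.exp(shape.kappa + shape.theta2 / 2.0)
    sd = mean * math.sqrt(math.exp(shape.theta2) - 1.0)
    return IsiStatistics(mean_isi=mean, sd_isi=sd)


def kl_divergence_bits(pref: LognormalShape, null: LognormalShape) -> float:
    """Discrimination information K (bits per ISI) from the preferred to the null density.

    Equals the KL divergence between the normal distributions of log-ISIs,
    converted to bits; invariant to the data scaling factor ``n`` because a
    common shift of ``kappa`` cancels in the difference.
    """
    t2p, t2n = pref.theta2, null.theta2
    nats = (
        0.5 * math.log(t2n / t2p)
        + (t2p + (pref.kappa - null.kappa) ** 2) / (2.0 * t2n)
        - 0.5
    )
    return nats / math.log(2.0)
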