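"""Stochastic decision evidence and rate-estimation utilities.

A trial presents ``N`` competing hypotheses (saccade targets) and ``C = N``
evidence channels, each a sequence of i.i.d. lognormal inter-spike intervals.
The channel matching the true motion direction draws from the
preferred-direction distribution (shorter ISIs); all others draw from the
null distribution.  Observations are divided by a hypothesis-independent
data scaling factor ``n`` before inference, which leaves inference invariant
but keeps the represented log-likelihood magnitudes in a plausible range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .parameters import ChannelPair, ParameterSet, default_registry, lognormal_shape

__all__ = [
    "Condition",
    "EvidenceBlock",
    "sample_evidence",
    "render_spike_train",
    "export_spike_trains",
    "moving_rate_statistics",
    "gaussian_smooth",
    "error_rate_target",
]


@dataclass(frozen=True)
class Condition:
    """One cell of the task grid: (number of alternatives, coherence, parameter set).

    ``correct_channel`` is the 1-based index of the channel drawing from the
    preferred-direction distribution; ``None`` means it is drawn uniformly
    per trial.
    """

    n_alternatives: int
    coherence: float | str
    parameter_set: str = "omega"
    scaling_n: float = 40.0
    correct_channel: int | None = None
    registry: dict[str, ParameterSet] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_alternatives < 2:
            raise ValueError("n_alternatives must be >= 2")
        if not self.scaling_n > 0:
            raise ValueError("scaling_n must be positive")
        if self.correct_channel is not None and not (
            1 <= self.correct_channel <= self.n_alternatives
        ):
            raise ValueError("correct_channel must be in [1, N]")
        self.pair()  # fail fast on unknown coherence / label

    def pair(self) -> ChannelPair:
        registry = self.registry if self.registry is not None else default_registry()
        try:
            pset = registry[self.parameter_set]
        except KeyError:
            raise KeyError(
                f"unknown parameter set {self.parameter_set!r}; "
                f"available: {sorted(registry)}"
            ) from None
        return pset.get(self.coherence)

    def shapes(self) -> tuple:
        """(preferred, null) lognormal shapes at this condition's scaling."""
        pair = self.pair()
        return (
            lognormal_shape(pair.preferred, self.scaling_n),
            lognormal_shape(pair.null, self.scaling_n),
        )

    def with_correct_channel(self, channel: int) -> "Condition":
        return replace(self, correct_channel=channel)


@dataclass(frozen=True)
class EvidenceBlock:
    """Scaled ISI observations, shape (channels, steps), plus the true channel."""

    observations: np.ndarray
    correct_channel: int

    def __post_init__(self) -> None:
        if np.any(self.observations <= 0):
            raise ValueError("all observations must be strictly positive")


def sample_evidence(
    condition: Condition, steps: int, rng: np.random.Generator
) -> EvidenceBlock:
    """Draw a (channels x steps) block of scaled lognormal ISI observations.

    The correct channel samples the preferred-direction lognormal; all other
    channels sample the null one.  Values are already divided by
    ``condition.scaling_n``.  Channels are sampled row by row so that a trial
    can be extended by drawing further blocks from the same generator.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    n = condition.n_alternatives
    correct = condition.correct_channel
    if correct is None:
        correct = int(rng.integers(1, n + 1))
    pref, null = condition.shapes()
    obs = np.empty((n, steps))
    for ch in range(n):
        shape = pref if ch + 1 == correct else null
        obs[ch] = np.exp(rng.normal(shape.kappa, shape.theta, size=steps))
    return EvidenceBlock(observations=obs, correct_channel=correct)


def render_spike_train(isi_sequence: np.ndarray) -> np.ndarray:
    """Event times (ms) of the spike train with the given ISI sequence.

    Event ``k`` occurs at the cumulative sum of the first ``k`` ISIs; an
    empty sequence renders an empty train.
    """
    isi = np.asarray(isi_sequence, dtype=float)
    if isi.size == 0:
        return isi
    if np.any(isi <= 0):
        raise ValueError("ISIs must be strictly positive")
    return np.cumsum(isi)


def export_spike_trains(spike_trains: list[np.ndarray], path) -> None:
    """Write spike trains as two-column delimited text (train_id, event_time_ms)."""
    import pandas as pd

    rows = [
        {"train_id": i, "event_time_ms": float(t)}
        for i, train in enumerate(spike_trains)
        for t in np.asarray(train, dtype=float)
    ]
    pd.DataFrame(rows, columns=["train_id", "event_time_ms"]).to_csv(
        path, index=False
    )


def moving_rate_statistics(
    spike_trains: list[np.ndarray],
    duration: float | None = None,
    window: float = 20.0,
    step: float = 1.0,
):
    """Across-train moving mean and variance of the firing rate.

    Spike counts are taken in a ``window``-ms window sliding every ``step``
    ms, divided by the window width (rates in spikes/ms; multiply by 1000
    for sp/s).  Only bins fully covered by data are returned: the last
    window starts at ``duration - window``, with ``duration`` defaulting to
    the latest event time across trains.

    Returns
    -------
    times, mean, variance : ndarray
        ``times`` are window-start times; ``mean``/``variance`` are the
        across-train statistics of the rate per bin.
    """
    if not window > 0:
        raise ValueError("window must be positive")
    if duration is None:
        duration = max((t[-1] for t in spike_trains if len(t)), default=window)
    starts = np.arange(0.0, duration - window + 0.5 * step, step)
    if starts.size == 0:
        starts = np.array([0.0])
    rates = np.empty((len(spike_trains), starts.size))
    for i, train in enumerate(spike_trains):
        t = np.asarray(train, dtype=float)
        # half-open windows (start, start + window] avoid double-counting
        # events that fall exactly on a window edge
        counts = np.searchsorted(t, starts + window, side="right") - np.searchsorted(
            t, starts, side="right"
        )
        rates[i] = counts / window
    mean = rates.mean(axis=0)
    var = rates.var(axis=0, ddof=1) if len(spike_trains) > 1 else np.zeros_like(mean)
    return starts, mean, var


def gaussian_smooth(series: np.ndarray, sd: float = 10.0, step: float = 1.0) -> np.ndarray:
    """Convolve a series with a unit-sum Gaussian kernel of SD ``sd`` (ms).

    The kernel is truncated at +/-4 SD (mass lost < 1e-4) and the input is
    edge-padded so the output has the input's length; a constant series is
    returned unchanged.
    """
    if not sd > 0:
        raise ValueError("sd must be positive")
    x = np.asarray(series, dtype=float)
    half = max(1, int(np.ceil(4.0 * sd / step)))
    grid = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (grid / sd) ** 2)
    kernel /= kernel.sum()
    padded = np.pad(x, half, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def error_rate_target(coherence: float, n_alternatives: int) -> float:
    """Target error rate for a coherence level (%): an exponential decay.

    The decay was fitted to monkey psychometric curves; intercepts are the
    chance error rates 1 - 1/N.  Only N = 2 and N = 4 are parameterised.
    """
    if coherence < 0:
        raise ValueError("coherence must be >= 0")
    s = float(coherence)
    if n_alternatives == 2:
        return 0.50 * np.exp(-0.11 * s)
    if n_alternatives == 4:
        return 0.75 * np.exp(-0.08 * s)
    raise ValueError(f"no error-rate target for N={n_alternatives} (supported: 2, 4)")
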