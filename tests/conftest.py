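import numpy as np
import pytest

from rmsprt.circuit import run_trial_with_traces
from rmsprt.evidence import Condition, error_rate_target
from rmsprt.inference import calibrate_threshold
from rmsprt.parameters import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def depleted_thetas():
    """Calibrated thresholds for the default depleted-registry grid.

    Session-scoped: shared by the behavioural closure, ordering and trace
    checks so the (expensive) calibration runs once.
    """
    sets = {2: "omega_d_n2", 4: "omega_d_n4"}
    thetas = {}
    for n_alt in (2, 4):
        for coh in ("3.2", "6.4", "12.8", "25.6", "51.2"):
            cond = Condition(n_alt, coh, sets[n_alt], 40.0)
            eps = error_rate_target(float(coh), n_alt)
            thetas[(n_alt, coh)] = calibrate_threshold(
                cond, eps, 10_000, np.random.default_rng([n_alt, int(10 * float(coh))])
            )
    return thetas


@pytest.fixture(scope="session")
def correct_traces(depleted_thetas):
    """800 circuit-mapped trials at 25.6% coherence (depleted set, N=2),
    keeping the correct ones — the standard trace-averaging sample."""
    cond = Condition(2, "25.6", "omega_d_n2", 40.0)
    theta = depleted_thetas[(2, "25.6")]
    rng = np.random.default_rng(2024)
    traces = []
    for _ in range(800):
        _, tr = run_trial_with_traces(cond, theta, None, rng)
        if tr.choice == tr.correct_channel:
            traces.append(tr)
    return traces
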