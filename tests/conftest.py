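import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import edprev
from edprev.config import ModelConfig
from edprev.synthetic import generate_world

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def world():
    """One fixed synthetic input bundle (seed 0, printed 15-18 population)."""
    return generate_world(0)


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def base_result(world, config):
    """Deterministic base-case evaluation, shared across tests."""
    return edprev.run_model(config, world)


def expm_series(a: np.ndarray, terms: int = 30) -> np.ndarray:
    """Independent matrix exponential: scaling-and-squaring Taylor series.

    Used as an oracle for the rate-to-probability embedding; deliberately
    avoids scipy's Pade implementation.
    """
    norm = float(np.abs(a).sum(axis=1).max())
    s = max(0, int(np.ceil(np.log2(norm))) + 1) if norm > 0 else 0
    b = a / (2.0**s)
    out = np.eye(a.shape[0])
    term = np.eye(a.shape[0])
    for k in range(1, terms):
        term = term @ b / k
        out = out + term
    for _ in range(s):
        out = out @ out
    return out


def microsimulate_cohort(
    matrices: list[np.ndarray],
    n_healthy: int,
    n_diseased: int,
    reps: int,
    rng: np.random.Generator,
):
    """Per-individual stochastic simulation of the four-state chain.

    Returns (mean occupancy, per-cycle Monte Carlo standard error of the
    mean) over ``reps`` replicate cohorts; the cohort engine's expected
    occupancy must agree within a few standard errors.
    """
    n = n_healthy + n_diseased
    total = reps * n
    states = np.zeros(total, dtype=np.int64)
    states.reshape(reps, n)[:, n_healthy:] = 1
    horizon = len(matrices)
    occ = np.zeros((horizon + 1, 4))
    se = np.zeros((horizon + 1, 4))

    def tally(t):
        counts = (states.reshape(reps, n)[:, :, None] == np.arange(4)).sum(axis=1)
        occ[t] = counts.mean(axis=0)
        se[t] = counts.std(axis=0, ddof=1) / np.sqrt(reps)

    tally(0)
    for t, p in enumerate(matrices):
        cum = np.cumsum(p, axis=1)
        u = rng.random(total)
        states = (u[:, None] > cum[states]).sum(axis=1)
        tally(t + 1)
    return occ, se
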