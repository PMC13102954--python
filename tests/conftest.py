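import numpy as np
import pytest

from fsdta.base_learner import BaseLearner, LearnerConfig, LinearProbe, ProbeRecord
from fsdta.synthetic import SyntheticConfig, generate_task_family
from fsdta.tasks import Task


@pytest.fixture(scope="session")
def tiny_family():
    """Small clean synthetic family shared across tests (read-only)."""
    return generate_task_family(SyntheticConfig(n_tasks=8, seed=7))


@pytest.fixture(scope="session")
def tiny_learner(tiny_family):
    return BaseLearner(LearnerConfig.tiny("GCN"), tiny_family.config.featurization)


@pytest.fixture
def probe():
    return LinearProbe()


def make_probe_task(seed: int, n: int = 8, slope: float = 1.5, noise: float = 0.3,
                    name: str = "probe") -> Task:
    """A linear-probe regression task with an even support/query split."""
    rng = np.random.default_rng(seed)
    xs = rng.normal(size=n)
    ys = slope * xs + noise * rng.normal(size=n)
    records = tuple(ProbeRecord(float(x), float(y)) for x, y in zip(xs, ys))
    half = n // 2
    return Task(name, records, tuple(range(half)), tuple(range(half, n)))
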