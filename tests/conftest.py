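import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crt_estimands import CRTDataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_dataset() -> CRTDataset:
    """Two treated clusters (sizes 2, 4) and two control clusters (2, 4).

    Hand enumeration: participant-level arm means are 2 and 1, so the
    unweighted contrast is 1.0; arm-wise means of cluster means are
    (4 + 1)/2 and (1 + 1)/2, so the equal-cluster-weight contrast is 1.5.
    """
    cluster = np.repeat(["t1", "t2", "c1", "c2"], [2, 4, 2, 4])
    arm = np.repeat([1, 1, 0, 0], [2, 4, 2, 4])
    y = np.array([3, 5, 1, 1, 1, 1, 0, 2, 1, 1, 1, 1], dtype=float)
    return CRTDataset(cluster=cluster, arm=arm, outcome=y)


def random_dataset(rng: np.random.Generator, min_clusters: int = 4) -> CRTDataset:
    """A random valid CRT dataset with unequal cluster sizes."""
    g = int(rng.integers(min_clusters, 13))
    sizes = rng.integers(1, 9, size=g)
    arms = np.zeros(g, dtype=int)
    arms[rng.permutation(g)[: g // 2]] = 1
    if arms.sum() in (0, g):  # pragma: no cover - g >= 4 guarantees a mix
        arms[0] = 1 - arms[0]
    cluster = np.repeat([f"g{i}" for i in range(g)], sizes)
    arm = np.repeat(arms, sizes)
    y = rng.normal(arm * 1.5, 2.0, size=sizes.sum())
    return CRTDataset(cluster=cluster, arm=arm, outcome=y)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220714)
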