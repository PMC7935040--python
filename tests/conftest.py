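import numpy as np
import pytest

from connctl import (
    CohortConfig,
    ConnectivityMatrix,
    RegionAtlas,
    generate_cohort,
)


@pytest.fixture
def atlas3():
    return RegionAtlas(names=("A", "B", "C"))


@pytest.fixture
def atlas4():
    return RegionAtlas(names=("A", "B", "C", "D"))


@pytest.fixture
def conn3(atlas3):
    w = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    return ConnectivityMatrix(weights=w, atlas=atlas3, subject_id="s1")


@pytest.fixture
def conn4_distinct(atlas4):
    """4 nodes, 6 distinct edge weights 1..6."""
    w = np.zeros((4, 4))
    vals = iter([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    for i in range(4):
        for j in range(i + 1, 4):
            w[i, j] = w[j, i] = next(vals)
    return ConnectivityMatrix(weights=w, atlas=atlas4, subject_id="s1")


@pytest.fixture
def small_cohort():
    """8 subjects x 20 regions, rGM coupled to topology."""
    return generate_cohort(
        CohortConfig(
            n_subjects=8, n_regions=20, rgm_topology_coupling=0.6, seed=42
        )
    )


def random_symmetric(n: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.uniform(0.0, 1.0, size=(n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w
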