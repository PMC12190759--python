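import numpy as np
import pytest

import ibexniche as ix


@pytest.fixture(scope="session")
def panel():
    return ix.default_panel()


@pytest.fixture(scope="session")
def small_config():
    """A compact two-genotype design used by several integration tests."""
    return ix.SimConfig(
        n_samples_per_genotype=2,
        n_lesions_per_sample=10,
        n_background_cells=500,
        field_size=(3000.0, 3000.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    cells, truth = ix.simulate_cells(small_config)
    return cells, truth


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-design simulation (3 mice/arm, 30 lesions/sample)."""
    cells, truth = ix.simulate_cells(ix.SimConfig(seed=1))
    return cells, truth


@pytest.fixture(scope="session")
def default_calls(default_dataset):
    cells, _ = default_dataset
    calls, report = ix.classify_cells(cells, seed=0)
    return calls, report


def brute_force_components(xy: np.ndarray, radius: float) -> list[set[int]]:
    """All-pairs union-find oracle for the proximity-graph partition."""
    n = len(xy)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    for i, j in zip(*np.nonzero(d2 <= radius**2)):
        if i < j:
            ri, rj = find(int(i)), find(int(j))
            if ri != rj:
                parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
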