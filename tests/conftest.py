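import numpy as np
import pytest
from hypothesis import settings

from funconn import BinaryGraph, CohortConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort that keeps every subject's 15%-sparsity graph
    connected (small modules leave between-module edges in the budget)."""
    config = CohortConfig(
        n_females_per_group=3, n_males_per_group=3,
        n_regions=45, n_modules=9, n_timepoints=120, seed=5,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-design cohort (76 subjects, 90 regions, 205 volumes)."""
    return generate_cohort(CohortConfig(seed=1))


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return BinaryGraph(a)


@pytest.fixture
def square_with_diagonal():
    """4-cycle 1-2-3-4 plus the 1-3 chord (0-indexed nodes 0..3)."""
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
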