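import numpy as np
import pytest

import stcarlocal as sc


@pytest.fixture
def pair_graph():
    """Two adjacent areas."""
    return sc.AdjacencyGraph(["a", "b"], np.array([[0, 1], [1, 0]]))


@pytest.fixture
def tiny_frame():
    """2 areas x 2 times, no covariates, expected counts populated."""
    frame = sc.StudyFrame(
        ["a", "b"],
        ["t0", "t1"],
        y=np.array([[2, 1], [0, 3]]),
        n=np.array([[50, 50], [50, 50]]),
        X=np.zeros((2, 2, 0)),
    )
    return sc.compute_expected_counts(frame)


@pytest.fixture
def lattice():
    return sc.make_lattice_graph(4, 4)


@pytest.fixture
def sim(lattice):
    """A small simulated panel with known truth."""
    return sc.simulate_dataset(lattice, J=2, seed=7)


def write_counts_csv(frame, path):
    frame.to_long().drop(columns=["E"], errors="ignore").to_csv(path, index=False)
    return path
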