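import numpy as np
import pytest

from pylortho import IdentityMatrix, activity_matrix, aligned_set


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_alignment():
    return aligned_set(
        [("a", "AAAA"), ("b", "CCCC"), ("c", "AACC")], alphabet="protein"
    )


@pytest.fixture
def hand_identity():
    """3-leaf identity matrix whose UPGMA trajectory is known by hand."""
    return IdentityMatrix(
        ("a", "b", "c"),
        np.array([[100, 90, 30], [90, 100, 50], [30, 50, 100]], dtype=float),
    )


@pytest.fixture
def doublet_matrix():
    """2x2 interaction matrix passing all orthogonality criteria (oc=6)."""
    return activity_matrix(
        np.array([[80.0, 10.0], [5.0, 60.0]]), ["t1", "t2"], ["s1", "s2"]
    )


def block_matrix(k: int, cognate: float = 90.0, cross: float = 0.0):
    """k fully orthogonal pairs: diagonal cognates, zero cross-reactivity."""
    vals = np.full((k, k), cross)
    np.fill_diagonal(vals, cognate)
    return activity_matrix(
        vals, [f"t{i}" for i in range(k)], [f"s{i}" for i in range(k)]
    )
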