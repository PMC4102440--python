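import numpy as np
import pytest

from chanvar.enm import CoarseStructure


@pytest.fixture
def random_cloud():
    """Factory: a seeded random coarse structure of n nodes in a box."""

    def make(seed: int = 0, n: int = 20, box: float = 12.0) -> CoarseStructure:
        rng = np.random.default_rng(seed)
        return CoarseStructure(
            residue_ids=np.arange(1, n + 1),
            chain_ids=np.array(["A"] * n, dtype=object),
            coords=rng.uniform(0.0, box, size=(n, 3)),
        )

    return make


@pytest.fixture
def three_node_chain() -> CoarseStructure:
    """Collinear nodes at 0, 5 and 10 A along x."""
    return CoarseStructure(
        residue_ids=np.array([1, 2, 3]),
        chain_ids=np.array(["A", "A", "A"], dtype=object),
        coords=np.array([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]]),
    )


@pytest.fixture
def two_nodes() -> CoarseStructure:
    return CoarseStructure(
        residue_ids=np.array([1, 2]),
        chain_ids=np.array(["A", "A"], dtype=object),
        coords=np.array([[0.0, 0, 0], [5.0, 0, 0]]),
    )


def random_rotation(seed: int) -> np.ndarray:
    """A uniformly random proper rotation matrix (QR-based)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
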