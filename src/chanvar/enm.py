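"""Elastic network models of coarse-grained protein structures.

The module implements the Gaussian network model (GNM) and the anisotropic
network model (ANM) for a structure coarse-grained to one node per residue.
Both models place uniform harmonic springs (force constant ``gamma``) between
every pair of nodes closer than a distance cutoff.  The GNM works with the
N x N Kirchhoff (connectivity) matrix and describes isotropic fluctuation
amplitudes; the ANM works with the 3N x 3N Hessian and resolves fluctuation
directions.  Eigen-decomposition of either matrix yields a spectrum of
collective modes; the slowest (smallest nonzero eigenvalue) modes describe
the large-scale, functionally relevant motions, such as the anti-correlated
movement of two domains about a hinge.

Units: distances are in Angstrom, the spring constant in energy/A^2, and
square fluctuations in units of kT/gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "CoarseStructure",
    "ElasticNetwork",
    "ModeSet",
    "MobilityProfile",
    "DomainPartition",
    "HingeReport",
    "build_kirchhoff",
    "build_hessian",
    "decompose_modes",
    "mode_square_fluctuations",
    "partition_by_mode",
    "find_hinges",
    "cross_correlation_map",
]

#: Largest node count accepted by the dense eigensolver.  Inputs beyond this
#: are rejected rather than silently taking unbounded time/memory.
MAX_NODES = 5000

DEFAULT_CUTOFF_GNM = 7.0
DEFAULT_CUTOFF_ANM = 15.0


class DisconnectedNetworkWarning(UserWarning):
    """A node (or component) of the elastic network has no contacts."""


@dataclass
class CoarseStructure:
    """One node per residue, at the C-alpha position for atomic input.

    Parameters
    ----------
    residue_ids : (N,) int array
        Residue numbers, unique within each chain.
    chain_ids : (N,) str array
        Chain label per node.
    coords : (N, 3) float array
        Node positions in Angstrom.
    source_tag : str
        Free-text provenance label.
    """

    residue_ids: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = self.coords.shape[0]
        if n < 2:
            raise ValueError("a coarse structure needs at least 2 nodes")
        if self.residue_ids.shape[0] != n or self.chain_ids.shape[0] != n:
            raise ValueError("residue_ids/chain_ids must match coords length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain_ids.tolist(), self.residue_ids.tolist()))
        if len(set(keys)) != n:
            raise ValueError("residue_ids must be unique within each chain")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]


@dataclass
class ElasticNetwork:
    """A built GNM Kirchhoff matrix or ANM Hessian with its parameters."""

    model_kind: str  # "GNM" or "ANM"
    cutoff: float
    gamma: float
    matrix: np.ndarray
    n_nodes: int


@dataclass
class ModeSet:
    """Eigen-decomposition of an elastic network.

    ``eigenvalues`` are ascending; the first ``zero_mode_count`` of them are
    numerically zero (rigid-body / disconnection modes).  Functional modes
    are indexed 1, 2, ... over the nonzero modes only, so mode 1 is the
    slowest collective motion.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns
    zero_mode_count: int
    model_kind: str
    n_nodes: int
    gamma: float = 1.0

    @property
    def n_nonzero(self) -> int:
        return self.eigenvalues.size - self.zero_mode_count

    def mode_column(self, mode_index: int) -> int:
        """Map a 1-based functional mode index to an eigenvector column."""
        if mode_index < 1 or mode_index > self.n_nonzero:
            raise ValueError(
                f"mode_index {mode_index} outside 1..{self.n_nonzero}"
            )
        return self.zero_mode_count + mode_index - 1

    def mode_eigenvalue(self, mode_index: int) -> float:
        return float(self.eigenvalues[self.mode_column(mode_index)])

    def residue_vectors(self, mode_index: int) -> np.ndarray:
        """Per-residue displacement of a functional mode.

        Returns an (N,) array for GNM and an (N, 3) array for ANM.
        """
        v = self.eigenvectors[:, self.mode_column(mode_index)]
        if self.model_kind == "ANM":
            return v.reshape(self.n_nodes, 3)
        return v


@dataclass
class MobilityProfile:
    """Per-residue square displacements (units kT/gamma)."""

    values: np.ndarray
    modes_used: list[int] = field(default_factory=list)


@dataclass
class DomainPartition:
    """Residue labels ("positive" / "negative" / "hinge") for one mode."""

    labels: np.ndarray
    mode_index: int


@dataclass
class HingeReport:
    """Hinge residues (0-based node indices) of one mode with amplitudes."""

    node_indices: np.ndarray
    amplitudes: np.ndarray
    mode_index: int


def _contact_matrix(structure: CoarseStructure, cutoff: float) -> np.ndarray:
    dists = squareform(pdist(structure.coords))
    contacts = (dists <= cutoff) & ~np.eye(structure.n_nodes, dtype=bool)
    if np.any(contacts.sum(axis=1) == 0):
        isolated = np.flatnonzero(contacts.sum(axis=1) == 0)
        warnings.warn(
            f"{isolated.size} node(s) have no neighbor within {cutoff} A; "
            "the elastic network is disconnected",
            DisconnectedNetworkWarning,
            stacklevel=3,
        )
    return contacts


def build_kirchhoff(
    structure: CoarseStructure,
    cutoff: float = DEFAULT_CUTOFF_GNM,
    gamma: float = 1.0,
) -> ElasticNetwork:
    """Build the GNM Kirchhoff (connectivity) matrix Gamma.

    Gamma_ij = -gamma for contacting pairs (inter-node distance <= cutoff),
    0 otherwise; the diagonal makes every row sum to zero.
    """
    if cutoff <= 0 or gamma <= 0:
        raise ValueError("cutoff and gamma must be positive")
    contacts = _contact_matrix(structure, cutoff)
    kirchhoff = -gamma * contacts.astype(float)
    np.fill_diagonal(kirchhoff, gamma * contacts.sum(axis=1))
    return ElasticNetwork("GNM", cutoff, gamma, kirchhoff, structure.n_nodes)


def build_hessian(
    structure: CoarseStructure,
    cutoff: float = DEFAULT_CUTOFF_ANM,
    gamma: float = 1.0,
) -> ElasticNetwork:
    """Build the 3N x 3N ANM Hessian.

    The off-diagonal super-element for a contacting pair is
    ``-(gamma / d_ij^2) * outer(r_ij, r_ij)``; diagonal super-elements are
    the negated sum of the off-diagonal ones in their row.
    """
    if cutoff <= 0 or gamma <= 0:
        raise ValueError("cutoff and gamma must be positive")
    n = structure.n_nodes
    coords = structure.coords
    contacts = _contact_matrix(structure, cutoff)
    dists = squareform(pdist(coords))
    if np.any(dists[contacts] == 0.0):
        raise ValueError("coincident nodes within cutoff: zero distance pair")
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contacts, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        rij = coords[j] - coords[i]
        block = -gamma * np.outer(rij, rij) / (rij @ rij)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return ElasticNetwork("ANM", cutoff, gamma, hessian, n)


def _fix_eigenvector_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the first component of significant magnitude positive.

    The sign of an eigenvector is arbitrary; fixing it makes domain
    partitions reproducible across platforms and LAPACK builds.
    """
    fixed = vectors.copy()
    for k in range(fixed.shape[1]):
        col = fixed[:, k]
        thresh = 1e-8 * np.max(np.abs(col))
        nz = np.flatnonzero(np.abs(col) > thresh)
        if nz.size and col[nz[0]] < 0:
            fixed[:, k] = -col
    return fixed


def decompose_modes(
    network: ElasticNetwork, zero_tol: float = 1e-8
) -> ModeSet:
    """Eigen-decompose an elastic network into collective modes.

    Eigenvalues are returned ascending; modes with
    ``lambda < zero_tol * lambda_max`` are flagged as zero (rigid-body)
    modes.  A connected GNM has exactly one zero mode; an ANM of a
    connected, non-collinear structure has exactly six.  More zero modes
    than expected indicate a disconnected (or collinear) structure and are
    reported with a warning, not an error.
    """
    matrix = network.matrix
    if matrix.shape[0] > 3 * MAX_NODES:
        raise ValueError(
            f"matrix of order {matrix.shape[0]} exceeds the dense-solver "
            f"contract ({MAX_NODES} nodes)"
        )
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("elastic network matrix must be symmetric")
    eigenvalues, eigenvectors = eigh(matrix)
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    lam_max = eigenvalues[-1] if eigenvalues.size else 0.0
    if lam_max == 0.0:  # null matrix: every mode is a zero mode
        zero_mode_count = eigenvalues.size
    else:
        zero_mode_count = int(np.sum(eigenvalues < zero_tol * lam_max))
    expected = 1 if network.model_kind == "GNM" else 6
    if zero_mode_count > expected:
        warnings.warn(
            f"{zero_mode_count} zero modes (expected {expected}): structure "
            "is disconnected or degenerate",
            DisconnectedNetworkWarning,
            stacklevel=2,
        )
    return ModeSet(
        eigenvalues=eigenvalues,
        eigenvectors=_fix_eigenvector_signs(eigenvectors),
        zero_mode_count=zero_mode_count,
        model_kind=network.model_kind,
        n_nodes=network.n_nodes,
        gamma=network.gamma,
    )


def mode_square_fluctuations(
    modes: ModeSet, k_slowest: int
) -> MobilityProfile:
    """Square displacement per residue from the ``k_slowest`` nonzero modes.

    Each mode k contributes ``(1 / lambda_k) * |v_k(residue)|^2``; for the
    ANM the three Cartesian components of a residue are summed.  Summing
    over *all* nonzero modes recovers the diagonal of the pseudo-inverse of
    the network matrix (a classical identity used as a test oracle).
    """
    if k_slowest < 1 or k_slowest > modes.n_nonzero:
        raise ValueError(
            f"k_slowest must be in 1..{modes.n_nonzero}, got {k_slowest}"
        )
    values = np.zeros(modes.n_nodes)
    used = list(range(1, k_slowest + 1))
    for idx in used:
        lam = modes.mode_eigenvalue(idx)
        v = modes.residue_vectors(idx)
        contrib = v**2 if v.ndim == 1 else np.sum(v**2, axis=1)
        values += contrib / lam
    return MobilityProfile(values=values / modes.gamma, modes_used=used)


def _mode_scalar_shape(modes: ModeSet, mode_index: int) -> np.ndarray:
    """Reduce a mode to one signed scalar per residue.

    GNM modes are already scalar.  An ANM mode is projected on its dominant
    displacement axis (first right singular vector of the N x 3 displacement
    matrix), which preserves the sign structure of the concerted motion.
    """
    v = modes.residue_vectors(mode_index)
    if v.ndim == 1:
        return v
    _, _, vt = np.linalg.svd(v, full_matrices=False)
    proj = v @ vt[0]
    # orient the axis so the convention matches the GNM sign fix
    thresh = 1e-8 * np.max(np.abs(proj))
    nz = np.flatnonzero(np.abs(proj) > thresh)
    if nz.size and proj[nz[0]] < 0:
        proj = -proj
    return proj


def partition_by_mode(
    modes: ModeSet, mode_index: int, hinge_band: float = 0.1
) -> DomainPartition:
    """Split residues into anti-correlated domains along one mode.

    Residues are labeled by the sign of their mode component; components
    with magnitude below ``hinge_band`` times the maximum magnitude are
    labeled "hinge" (the nearly immobile boundary mediating the concerted
    motion).
    """
    if not 0 <= hinge_band < 1:
        raise ValueError("hinge_band must be in [0, 1)")
    shape = _mode_scalar_shape(modes, mode_index)
    band = hinge_band * np.max(np.abs(shape))
    labels = np.where(shape > 0, "positive", "negative").astype(object)
    labels[np.abs(shape) <= band] = "hinge"
    return DomainPartition(labels=labels, mode_index=mode_index)


def find_hinges(
    modes: ModeSet, mode_index: int, hinge_band: float = 0.1
) -> HingeReport:
    """Locate hinge residues of a mode.

    The hinge set is the union of residues inside the hinge band and
    residues flanking a sign change between consecutive non-hinge residues.
    A constant-sign mode has no hinge and triggers a warning.
    """
    shape = _mode_scalar_shape(modes, mode_index)
    partition = partition_by_mode(modes, mode_index, hinge_band)
    labels = partition.labels
    hinge = set(np.flatnonzero(labels == "hinge").tolist())
    for i in range(len(labels) - 1):
        a, b = labels[i], labels[i + 1]
        if {a, b} == {"positive", "negative"}:
            hinge.update((i, i + 1))
    if "positive" not in labels or "negative" not in labels:
        warnings.warn(
            f"mode {mode_index} has constant sign: no anti-correlated "
            "partition, hinge report may be empty",
            UserWarning,
            stacklevel=2,
        )
    indices = np.array(sorted(hinge), dtype=int)
    return HingeReport(
        node_indices=indices,
        amplitudes=np.abs(shape[indices]) if indices.size else np.array([]),
        mode_index=mode_index,
    )


def cross_correlation_map(modes: ModeSet, k_slowest: int) -> np.ndarray:
    """Normalized residue-residue fluctuation correlations.

    C_ij = cov_ij / sqrt(cov_ii * cov_jj) accumulated over the ``k_slowest``
    nonzero modes.  Values near -1 mark pairs moving in opposite directions
    (anti-correlated domains).  Residues with zero self-covariance yield
    NaN entries and a warning.
    """
    if k_slowest < 1 or k_slowest > modes.n_nonzero:
        raise ValueError(
            f"k_slowest must be in 1..{modes.n_nonzero}, got {k_slowest}"
        )
    cov = np.zeros((modes.n_nodes, modes.n_nodes))
    for idx in range(1, k_slowest + 1):
        lam = modes.mode_eigenvalue(idx)
        v = modes.residue_vectors(idx)
        if v.ndim == 1:
            cov += np.outer(v, v) / lam
        else:
            cov += (v @ v.T) / lam
    diag = np.diag(cov).copy()
    if np.any(diag <= 0):
        warnings.warn(
            "residue(s) with zero self-covariance: correlation undefined "
            "(NaN) for those entries",
            UserWarning,
            stacklevel=2,
        )
        diag[diag <= 0] = np.nan
    norm = np.sqrt(np.outer(diag, diag))
    with np.errstate(invalid="ignore"):
        corr = cov / norm
    return np.clip(corr, -1.0, 1.0)
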