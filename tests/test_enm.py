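"""Elastic-network construction, mode decomposition and hinge detection."""

import numpy as np
import pytest

from chanvar import enm
from chanvar.enm import (
    CoarseStructure,
    DisconnectedNetworkWarning,
    ModeSet,
    build_hessian,
    build_kirchhoff,
    cross_correlation_map,
    decompose_modes,
    find_hinges,
    mode_square_fluctuations,
    partition_by_mode,
)
from chanvar.simulate import gen_elastic_toy

from conftest import random_rotation


def brute_force_kirchhoff(coords, cutoff, gamma):
    n = coords.shape[0]
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                k[i, j] = -gamma
                k[i, i] += gamma
    return k


def brute_force_hessian(coords, cutoff, gamma):
    n = coords.shape[0]
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij = coords[j] - coords[i]
            d = np.linalg.norm(rij)
            if d <= cutoff:
                block = -gamma * np.outer(rij, rij) / d**2
                h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
                h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
    return h


class TestKirchhoff:
    def test_two_nodes_within_cutoff(self, two_nodes):
        net = build_kirchhoff(two_nodes, cutoff=7.0, gamma=1.0)
        assert np.array_equal(net.matrix, [[1, -1], [-1, 1]])

    def test_three_node_chain_adjacent_contacts_only(self, three_node_chain):
        net = build_kirchhoff(three_node_chain, cutoff=7.0, gamma=1.0)
        expected = [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        assert np.array_equal(net.matrix, expected)

    def test_matches_brute_force_on_random_cloud(self, random_cloud):
        structure = random_cloud(seed=3, n=20)
        net = build_kirchhoff(structure, cutoff=7.0, gamma=2.0)
        oracle = brute_force_kirchhoff(structure.coords, 7.0, 2.0)
        assert np.array_equal(net.matrix, oracle)

    @pytest.mark.parametrize("seed", range(5))
    def test_row_sums_zero(self, random_cloud, seed):
        structure = random_cloud(seed=seed, n=30)
        net = build_kirchhoff(structure, cutoff=8.0, gamma=1.5)
        assert np.all(np.abs(net.matrix.sum(axis=1)) < 1e-10 * net.gamma)

    def test_fewer_than_two_nodes_rejected(self):
        with pytest.raises(ValueError, match="at least 2 nodes"):
            CoarseStructure(np.array([1]), np.array(["A"], dtype=object),
                            np.zeros((1, 3)))

    def test_isolated_node_warns(self, three_node_chain):
        with pytest.warns(DisconnectedNetworkWarning):
            build_kirchhoff(three_node_chain, cutoff=2.0)


class TestHessian:
    def test_two_nodes_along_x(self, two_nodes):
        net = build_hessian(two_nodes, cutoff=7.0, gamma=1.0)
        off = net.matrix[0:3, 3:6]
        assert np.allclose(off, -np.diag([1.0, 0.0, 0.0]))

    def test_tetrahedron_matches_brute_force(self):
        coords = np.array([
            [1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
        ]) * 2.0
        structure = CoarseStructure(np.arange(1, 5),
                                    np.array(["A"] * 4, dtype=object), coords)
        net = build_hessian(structure, cutoff=10.0, gamma=1.3)
        assert np.allclose(net.matrix,
                           brute_force_hessian(coords, 10.0, 1.3), atol=1e-12)

    def test_no_contacts_gives_zero_matrix_and_warning(self, two_nodes):
        with pytest.warns(DisconnectedNetworkWarning):
            net = build_hessian(two_nodes, cutoff=1.0)
        assert np.all(net.matrix == 0.0)

    def test_coincident_nodes_rejected(self):
        structure = CoarseStructure(
            np.array([1, 2]), np.array(["A", "A"], dtype=object),
            np.zeros((2, 3)),
        )
        with pytest.raises(ValueError, match="oincident"):
            build_hessian(structure, cutoff=5.0)


class TestDecompose:
    def test_two_node_gnm_spectrum(self, two_nodes):
        modes = decompose_modes(build_kirchhoff(two_nodes, 7.0))
        assert np.allclose(modes.eigenvalues, [0.0, 2.0], atol=1e-12)
        assert modes.zero_mode_count == 1

    def test_three_node_chain_spectrum(self, three_node_chain):
        modes = decompose_modes(build_kirchhoff(three_node_chain, 7.0))
        assert np.allclose(modes.eigenvalues, [0.0, 1.0, 3.0], atol=1e-12)

    def test_eigenvectors_orthonormal(self, random_cloud):
        structure = random_cloud(seed=1, n=25)
        modes = decompose_modes(build_kirchhoff(structure, 12.0))
        v = modes.eigenvectors
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)

    def test_anm_two_nodes_has_five_zero_modes(self, two_nodes):
        # a collinear two-body system: 3 translations + 2 rotations
        modes = decompose_modes(build_hessian(two_nodes, 7.0))
        assert modes.zero_mode_count == 5

    def test_disconnected_gnm_flagged_not_fatal(self, three_node_chain):
        with pytest.warns(DisconnectedNetworkWarning):
            net = build_kirchhoff(three_node_chain, cutoff=2.0)
            modes = decompose_modes(net)
        assert modes.zero_mode_count == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_anm_eigenvalues_rigid_motion_invariant(self, random_cloud, seed):
        structure = random_cloud(seed=seed, n=15)
        rot = random_rotation(seed + 100)
        moved = CoarseStructure(
            structure.residue_ids, structure.chain_ids,
            structure.coords @ rot.T + np.array([3.0, -7.0, 11.0]),
        )
        ev_a = decompose_modes(build_hessian(structure, 15.0)).eigenvalues
        ev_b = decompose_modes(build_hessian(moved, 15.0)).eigenvalues
        assert np.allclose(ev_a, ev_b, atol=1e-8)


class TestSquareFluctuations:
    def test_two_node_single_mode(self, two_nodes):
        modes = decompose_modes(build_kirchhoff(two_nodes, 7.0))
        profile = mode_square_fluctuations(modes, 1)
        assert np.allclose(profile.values, [0.25, 0.25])

    @pytest.mark.parametrize("seed", range(5))
    def test_all_modes_equal_pseudoinverse_diagonal(self, random_cloud, seed):
        structure = random_cloud(seed=seed, n=20)
        net = build_kirchhoff(structure, 12.0, gamma=1.0)
        modes = decompose_modes(net)
        profile = mode_square_fluctuations(modes, modes.n_nonzero)
        oracle = np.diag(np.linalg.pinv(net.matrix, rcond=1e-8,
                                        hermitian=True))
        assert np.allclose(profile.values, oracle, atol=1e-8)

    def test_anm_all_modes_equal_pseudoinverse_blocks(self, random_cloud):
        structure = random_cloud(seed=2, n=12)
        net = build_hessian(structure, 15.0)
        modes = decompose_modes(net)
        profile = mode_square_fluctuations(modes, modes.n_nonzero)
        pinv = np.linalg.pinv(net.matrix, rcond=1e-8, hermitian=True)
        oracle = np.diag(pinv).reshape(-1, 3).sum(axis=1)
        assert np.allclose(profile.values, oracle, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_dumbbell_minimum_at_linker(self, seed):
        structure, truth = gen_elastic_toy(seed=seed)
        modes = decompose_modes(build_kirchhoff(structure, 7.0))
        profile = mode_square_fluctuations(modes, 2)
        lo, hi = truth.params["linker_range"]
        assert lo <= int(np.argmin(profile.values)) <= hi
        assert profile.values.min() < np.median(profile.values)

    def test_k_beyond_available_modes_rejected(self, two_nodes):
        modes = decompose_modes(build_kirchhoff(two_nodes, 7.0))
        with pytest.raises(ValueError, match="k_slowest"):
            mode_square_fluctuations(modes, 2)


def synthetic_gnm_modeset(eigenvalues, eigenvectors):
    eigenvectors = np.asarray(eigenvectors, dtype=float)
    return ModeSet(
        eigenvalues=np.asarray(eigenvalues, dtype=float),
        eigenvectors=eigenvectors /
        np.linalg.norm(eigenvectors, axis=0, keepdims=True),
        zero_mode_count=1,
        model_kind="GNM",
        n_nodes=eigenvectors.shape[0],
    )


class TestPartitionAndHinges:
    def test_three_node_chain_partition(self, three_node_chain):
        modes = decompose_modes(build_kirchhoff(three_node_chain, 7.0))
        part = partition_by_mode(modes, 1, hinge_band=0.1)
        assert list(part.labels) == ["positive", "hinge", "negative"]

    def test_two_node_partition(self, two_nodes):
        modes = decompose_modes(build_kirchhoff(two_nodes, 7.0))
        part = partition_by_mode(modes, 1, hinge_band=0.0)
        assert set(part.labels) == {"positive", "negative"}

    def test_three_node_chain_hinge_is_middle_node(self, three_node_chain):
        modes = decompose_modes(build_kirchhoff(three_node_chain, 7.0))
        report = find_hinges(modes, 1, hinge_band=0.1)
        assert report.node_indices.tolist() == [1]

    def test_sign_boundary_without_small_components(self):
        ones = np.ones(4) / 2.0
        shape = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
        modes = synthetic_gnm_modeset(
            [0.0, 1.0], np.column_stack([ones, shape])
        )
        report = find_hinges(modes, 1, hinge_band=0.1)
        assert report.node_indices.tolist() == [1, 2]

    def test_constant_sign_mode_empty_hinge_with_warning(self):
        ones = np.ones(4)
        modes = synthetic_gnm_modeset(
            [0.0, 1.0], np.column_stack([ones, ones])
        )
        with pytest.warns(UserWarning, match="constant sign"):
            report = find_hinges(modes, 1, hinge_band=0.1)
        assert report.node_indices.size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_dumbbell_domains_oppositely_labeled(self, seed):
        structure, truth = gen_elastic_toy(seed=seed)
        modes = decompose_modes(build_kirchhoff(structure, 7.0))
        part = partition_by_mode(modes, 1, hinge_band=0.1)
        a_lo, a_hi = truth.params["domain_a_range"]
        b_lo, b_hi = truth.params["domain_b_range"]
        label_a = set(part.labels[a_lo:a_hi + 1]) - {"hinge"}
        label_b = set(part.labels[b_lo:b_hi + 1]) - {"hinge"}
        assert label_a == {"positive"} and label_b == {"negative"} or \
            label_a == {"negative"} and label_b == {"positive"}

    def test_invalid_hinge_band_rejected(self, two_nodes):
        modes = decompose_modes(build_kirchhoff(two_nodes, 7.0))
        with pytest.raises(ValueError, match="hinge_band"):
            partition_by_mode(modes, 1, hinge_band=1.0)


class TestCrossCorrelation:
    def test_two_node_perfect_anticorrelation(self, two_nodes):
        modes = decompose_modes(build_kirchhoff(two_nodes, 7.0))
        corr = cross_correlation_map(modes, 1)
        assert corr[0, 1] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_all_modes_match_pseudoinverse_oracle(self, random_cloud):
        structure = random_cloud(seed=5, n=18)
        net = build_kirchhoff(structure, 12.0)
        modes = decompose_modes(net)
        corr = cross_correlation_map(modes, modes.n_nonzero)
        cov = np.linalg.pinv(net.matrix, rcond=1e-8, hermitian=True)
        d = np.sqrt(np.diag(cov))
        oracle = cov / np.outer(d, d)
        assert np.allclose(corr, oracle, atol=1e-8)

    def test_dumbbell_interdomain_anticorrelated(self):
        structure, truth = gen_elastic_toy(seed=6)
        modes = decompose_modes(build_kirchhoff(structure, 7.0))
        corr = cross_correlation_map(modes, 2)
        a_lo, a_hi = truth.params["domain_a_range"]
        b_lo, b_hi = truth.params["domain_b_range"]
        inter = corr[a_lo:a_hi + 1, b_lo:b_hi + 1]
        assert inter.mean() < 0.0

    def test_bounds_and_symmetry(self, random_cloud):
        structure = random_cloud(seed=8, n=15)
        modes = decompose_modes(build_kirchhoff(structure, 12.0))
        corr = cross_correlation_map(modes, 3)
        assert np.all(corr >= -1.0) and np.all(corr <= 1.0)
        assert np.allclose(corr, corr.T)


def test_oversize_structure_rejected(monkeypatch):
    monkeypatch.setattr(enm, "MAX_NODES", 4)
    net = enm.ElasticNetwork("ANM", 15.0, 1.0, np.zeros((15, 15)), 5)
    with pytest.raises(ValueError, match="dense-solver"):
        decompose_modes(net)
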