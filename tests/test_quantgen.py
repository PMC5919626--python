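"""Breeder's-equation responses, gradients, angles and rankings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from protqg.quantgen import (
    constraint_angle,
    differential_gradient,
    per_residue_gradient,
    rank_residues,
    realized_response,
    response_to_selection,
    selection_gradient,
    subspace_angle,
)

nonzero_vectors = arrays(
    float,
    st.integers(2, 6),
    elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
).filter(lambda v: np.linalg.norm(v) > 1e-6)


class TestResponseToSelection:
    def test_identity_matrix_returns_beta(self):
        assert np.allclose(response_to_selection(np.eye(3), [1, 2, 3]), [1, 2, 3])

    def test_zero_matrix_is_absolute_constraint(self):
        assert np.allclose(response_to_selection(np.zeros((3, 3)), [1, 2, 3]), 0.0)

    def test_diagonal_scaling(self):
        assert np.allclose(response_to_selection(np.diag([2.0, 1.0]), [1, 1]), [2, 1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            response_to_selection(np.eye(3), [1, 2])


class TestRealizedResponse:
    def test_identical_means_give_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(realized_response(v, v), 0.0)

    def test_elementwise_difference(self):
        assert np.allclose(realized_response([1, 1, 1], [0, 1, 2]), [1, 0, -1])

    def test_antisymmetry(self):
        a, b = np.array([3.0, -1.0]), np.array([0.5, 2.0])
        assert np.allclose(realized_response(a, b), -realized_response(b, a))

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            realized_response([1, 2, 3], [1, 2])


class TestSelectionGradient:
    def test_identity_matrix(self):
        dz = np.array([3.0, -1.0, 2.0])
        assert np.allclose(selection_gradient(np.eye(3), dz), dz)

    def test_diagonal_matrix(self):
        assert np.allclose(selection_gradient(np.diag([2.0, 1.0]), [2, 1]), [1, 1])

    def test_pseudo_inverse_annihilates_null_directions(self):
        assert np.allclose(selection_gradient(np.diag([1.0, 0.0]), [1, 1]), [1, 0])

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            selection_gradient(np.zeros((2, 2)), [1, 1])

    def test_ridge_alternative(self):
        G = np.diag([1.0, 0.0])
        beta = selection_gradient(G, [1.0, 1.0], ridge=1e-6)
        assert beta[0] == pytest.approx(1.0, rel=1e-4)
        assert beta[1] == pytest.approx(1e6, rel=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_response_roundtrip_projects_onto_range(self, seed):
        rng = np.random.default_rng(seed)
        l, r = 12, 4
        A = rng.normal(size=(l, r))
        G = A @ A.T  # rank r PSD
        dz = rng.normal(size=l)
        beta = selection_gradient(G, dz)
        # G beta equals the projection of dz onto range(G).
        Q, _ = np.linalg.qr(A)
        proj = Q @ (Q.T @ dz)
        assert np.allclose(response_to_selection(G, beta), proj, atol=1e-8)
        # For dz already in range(G), the roundtrip is exact.
        dz_in = A @ rng.normal(size=r)
        beta_in = selection_gradient(G, dz_in)
        assert np.allclose(response_to_selection(G, beta_in), dz_in, atol=1e-8)


class TestDifferentialGradient:
    def test_identity_phenotypic_covariance(self):
        assert np.allclose(differential_gradient(np.eye(2), [3, 4]), [3, 4])

    def test_scaled_identity(self):
        assert np.allclose(differential_gradient(2 * np.eye(2), [2, 4]), [1, 2])

    def test_singular_matrix_via_pseudo_inverse(self):
        assert np.allclose(differential_gradient(np.diag([1.0, 0.0]), [2, 5]), [2, 0])


class TestConstraintAngle:
    def test_parallel_is_zero(self):
        assert constraint_angle([1, 0], [2, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_is_ninety(self):
        assert constraint_angle([1, 0], [0, 1]) == pytest.approx(90.0, abs=1e-9)

    def test_forty_five_degrees(self):
        assert constraint_angle([1, 1], [1, 0]) == pytest.approx(45.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            constraint_angle([0, 0], [1, 0])

    @settings(deadline=None, derandomize=True)
    @given(nonzero_vectors)
    def test_self_angle_zero_and_opposite_angle_180(self, v):
        assert constraint_angle(v, v) == pytest.approx(0.0, abs=1e-9)
        assert constraint_angle(v, -v) == pytest.approx(180.0, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(nonzero_vectors, st.floats(1e-3, 1e3))
    def test_invariant_to_positive_rescaling(self, v, c):
        w = v + 1.0  # make the pair non-degenerate but fixed
        if np.linalg.norm(w) < 1e-6:
            return
        assert constraint_angle(v, w) == pytest.approx(constraint_angle(c * v, w), abs=1e-6)
        assert constraint_angle(v, w) == pytest.approx(constraint_angle(v, c * w), abs=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(nonzero_vectors, st.floats(0.1, 10.0))
    def test_isotropic_g_means_no_constraint(self, dz, c):
        G = c * np.eye(len(dz))
        beta = selection_gradient(G, dz)
        assert constraint_angle(dz, beta) == pytest.approx(0.0, abs=1e-6)


class TestSubspaceAngle:
    def test_leading_eigenvector_is_in_subspace(self):
        G = np.diag([10.0, 1.0, 0.1])
        assert subspace_angle([1, 0, 0], G) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_to_retained_subspace(self):
        # 99% of variance sits in the first axis alone.
        G = np.diag([1000.0, 1.0])
        assert subspace_angle([0, 1], G, variance_fraction=0.99) == pytest.approx(
            90.0, abs=1e-9
        )

    def test_forty_five_degree_construction(self):
        G = np.diag([1000.0, 1.0])
        v = np.array([1.0, 1.0]) / np.sqrt(2.0)
        assert subspace_angle(v, G, variance_fraction=0.99) == pytest.approx(45.0, abs=1e-9)

    def test_full_fraction_keeps_everything(self):
        G = np.diag([3.0, 2.0, 1.0])
        assert subspace_angle([1, 1, 1], G, variance_fraction=1.0) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_no_positive_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            subspace_angle([1, 0], -np.eye(2))


class TestPerResidueGradient:
    def test_min_max_standardization(self):
        beta = np.array([4.0, 0, 0, 0, 0, 0, 2.0, 0, 0])
        assert np.allclose(per_residue_gradient(beta), [1.0, 0.0, 0.5])

    def test_single_hot_residue(self):
        beta = np.zeros(9)
        beta[4] = -3.0
        assert np.allclose(per_residue_gradient(beta), [0.0, 1.0, 0.0])

    def test_uniform_gradient_degenerates_to_zero(self):
        beta = np.ones(12)
        assert np.allclose(per_residue_gradient(beta), 0.0)

    def test_bounds_and_extremes(self):
        rng = np.random.default_rng(0)
        out = per_residue_gradient(rng.normal(size=30))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            per_residue_gradient(np.ones(4))


class TestRankResidues:
    def test_signs_route_to_tables(self):
        beta = np.array([1.0, 0, 0, -1.0, 0, 0])
        dz = np.zeros(6)
        directional, purifying = rank_residues(beta, dz, top=1)
        assert directional["residue_index"].tolist() == [1]
        assert purifying["residue_index"].tolist() == [2]

    def test_all_positive_beta_empties_purifying_table(self):
        beta = np.ones(6)
        _, purifying = rank_residues(beta, np.zeros(6), top=2)
        assert len(purifying) == 0

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(7)
        k = 20
        beta = rng.normal(size=3 * k)
        dz = rng.normal(size=3 * k)
        directional, purifying = rank_residues(beta, dz, top=k)
        b3 = beta.reshape(k, 3)
        dir_oracle = sorted(
            (j + 1 for j in range(k) if (b3[j] > 0).any()),
            key=lambda j: -np.abs(b3[j - 1]).sum(),
        )
        pur_oracle = sorted(
            (j + 1 for j in range(k) if (b3[j] < 0).any()),
            key=lambda j: b3[j - 1].sum(),
        )
        assert directional["residue_index"].tolist() == dir_oracle
        assert purifying["residue_index"].tolist() == pur_oracle

    def test_top_larger_than_k_warns_and_returns_all(self):
        beta = np.array([1.0, -1.0, 0.5, 0.2, -0.3, 0.1])
        with pytest.warns(UserWarning, match="top"):
            directional, _ = rank_residues(beta, np.zeros(6), top=10)
        assert len(directional) == 2

    def test_labels_are_carried_through(self):
        beta = np.array([0.0, 0.0, 2.0, 1.0, 0.0, 0.0])
        labels = [(112, "TYR"), (80, "HIS")]
        directional, _ = rank_residues(beta, np.zeros(6), top=2, labels=labels)
        assert directional.loc[0, "residue_index"] == 112
        assert directional.loc[0, "residue_name"] == "TYR"
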