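"""Bilinear element kinematics: shape functions, deformation gradient, strain."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from quadpoisson import (
    DeformationPair,
    MarkerQuad,
    deformation_gradient_at,
    element_strain,
    shape_functions,
    strain_at,
)
from quadpoisson.calibration import rotation_matrix
from quadpoisson.element import GAUSS_POINTS, shape_function_gradients
from quadpoisson.errors import ConfigurationError, DegenerateElementError, InvalidQuadError
from conftest import random_convex_quad, random_simple_quad

UNIT_SQUARE = [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


class TestShapeFunctions:
    def test_centroid_and_nodes(self):
        assert np.allclose(shape_functions(0, 0), [0.25] * 4)
        assert np.allclose(shape_functions(-1, -1), [1, 0, 0, 0])
        assert np.allclose(shape_functions(1, 1), [0, 0, 1, 0])

    def test_partition_of_unity_and_linear_completeness(self):
        """Weights sum to 1 and reproduce (xi, eta) on the reference square,
        at 10^4 random natural-coordinate points."""
        rng = np.random.default_rng(42)
        corners = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
        for xi, eta in rng.uniform(-1, 1, size=(10_000, 2)):
            n = shape_functions(xi, eta)
            assert abs(n.sum() - 1.0) < 1e-12
            assert np.allclose(n @ corners, [xi, eta], atol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ConfigurationError):
            shape_functions(1.5, 0)
        with pytest.raises(ConfigurationError):
            shape_function_gradients(0, -1.01)


class TestDeformationGradient:
    def test_affine_stretch(self):
        pair = DeformationPair.from_arrays(UNIT_SQUARE, np.array(UNIT_SQUARE) @ np.diag([0.92, 1.40]))
        for xi, eta in [(0, 0), (0.3, -0.7), *GAUSS_POINTS]:
            assert np.allclose(deformation_gradient_at(pair, xi, eta), np.diag([0.92, 1.40]), atol=1e-12)

    def test_pure_rigid_rotation(self):
        r = rotation_matrix(math.radians(25))
        pair = DeformationPair.from_arrays(UNIT_SQUARE, np.array(UNIT_SQUARE) @ r.T)
        assert np.allclose(deformation_gradient_at(pair, 0.4, 0.4), r, atol=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_affine_map_oracle(self, seed):
        """For random convex quads and random invertible linear maps (det > 0),
        F equals the map's linear part at random interior points."""
        rng = np.random.default_rng(seed)
        quad = random_convex_quad(seed)
        a = rng.normal(0, 0.5, (2, 2)) + np.eye(2)
        if np.linalg.det(a) <= 0.05:
            a = a @ np.diag([1, -1]) if np.linalg.det(a) < -0.05 else np.eye(2) * 1.1
        t = rng.normal(0, 5, 2)
        pair = DeformationPair(quad, quad.transformed(a, t))
        for xi, eta in rng.uniform(-0.99, 0.99, (5, 2)):
            assert np.allclose(deformation_gradient_at(pair, xi, eta), a, atol=1e-10)

    def test_finite_difference_oracle_single_vertex_displacement(self):
        """Bilinear (non-affine) displacement field checked against central
        finite differences of the interpolated displacements."""
        initial = np.array(UNIT_SQUARE)
        deformed = initial.copy()
        deformed[0] += [0.01, 0.0]
        pair = DeformationPair.from_arrays(initial, deformed)
        h = 1e-6
        disp = deformed - initial
        for xi, eta in [(0.0, 0.0), (0.37, -0.81), *GAUSS_POINTS]:
            grads = shape_function_gradients(xi, eta)
            jac = initial.T @ grads
            du_dnat = np.column_stack(
                [
                    (shape_functions(xi + h, eta) - shape_functions(xi - h, eta)) @ disp / (2 * h),
                    (shape_functions(xi, eta + h) - shape_functions(xi, eta - h)) @ disp / (2 * h),
                ]
            )
            f_expected = np.eye(2) + du_dnat @ np.linalg.inv(jac)
            assert np.allclose(deformation_gradient_at(pair, xi, eta), f_expected, atol=1e-8)

    def test_degenerate_jacobian_named_in_error(self):
        """A dart (simple but non-convex) quad is accepted, but evaluation at
        its reflex corner reports the offending natural coordinates."""
        dart = MarkerQuad([(0, 0), (4, 0), (4, 4), (1, 1)])
        pair = DeformationPair(dart, dart.transformed(translation=(0, 0.1)))
        assert np.allclose(deformation_gradient_at(pair, 0, 0), np.eye(2), atol=1e-12)
        with pytest.raises(DegenerateElementError, match=r"\(-1, 1\)"):
            deformation_gradient_at(pair, -1, 1)


class TestStrainMeasures:
    def test_small_strain_worked_example(self, worked_pair):
        t = strain_at(worked_pair, measure="small")
        assert t.exx == pytest.approx(-0.08, abs=1e-12)
        assert t.eyy == pytest.approx(0.40, abs=1e-12)
        assert t.exy == pytest.approx(0.0, abs=1e-12)

    def test_green_lagrange_zero_under_rigid_rotation(self):
        r = rotation_matrix(math.radians(33))
        pair = DeformationPair.from_arrays(UNIT_SQUARE, np.array(UNIT_SQUARE) @ r.T)
        t = strain_at(pair, measure="green_lagrange")
        assert np.allclose(t.as_matrix(), 0.0, atol=1e-12)

    def test_green_lagrange_closed_form_uniaxial(self):
        pair = DeformationPair.from_arrays(UNIT_SQUARE, np.array(UNIT_SQUARE) @ np.diag([1.0, 1.4]))
        t = strain_at(pair, measure="green_lagrange")
        assert t.eyy == pytest.approx((1.4**2 - 1) / 2, abs=1e-12)  # 0.48

    def test_biot_principal_values_are_stretch_minus_one(self):
        pair = DeformationPair.from_arrays(UNIT_SQUARE, np.array(UNIT_SQUARE) @ np.diag([0.92, 1.40]))
        t = strain_at(pair, measure="biot")
        assert t.exx == pytest.approx(-0.08, abs=1e-12)
        assert t.eyy == pytest.approx(0.40, abs=1e-12)

    def test_unknown_measure(self, worked_pair):
        with pytest.raises(ConfigurationError):
            strain_at(worked_pair, measure="hencky")


class TestElementStrain:
    def test_affine_modes_agree_with_zero_heterogeneity(self, worked_pair):
        tc, hc = element_strain(worked_pair, "centroid")
        tg, hg = element_strain(worked_pair, "gauss_mean")
        assert np.allclose(tc.as_matrix(), tg.as_matrix(), atol=1e-14)
        assert hc == pytest.approx(0.0, abs=1e-12)
        assert hg == pytest.approx(0.0, abs=1e-12)

    def test_hourglass_mode_flags_heterogeneity(self):
        """The alternating (+d, -d) x-displacement pattern produces zero strain
        at the element centre but nonzero strain at the Gauss points."""
        initial = np.array(UNIT_SQUARE)
        deformed = initial + np.array([[0.01, 0], [-0.01, 0], [0.01, 0], [-0.01, 0]])
        pair = DeformationPair.from_arrays(initial, deformed)
        tc, hetero = element_strain(pair, "centroid")
        assert np.allclose(tc.as_matrix(), 0.0, atol=1e-14)
        assert hetero > 1e-3
        g = strain_at(pair, *GAUSS_POINTS[0])
        assert np.linalg.norm(g.as_matrix()) > 1e-3

    def test_unknown_mode(self, worked_pair):
        with pytest.raises(ConfigurationError):
            element_strain(worked_pair, mode="nodal")


class TestInvariances:
    @pytest.mark.parametrize("angle_deg", [25.0, 32.0])
    def test_co_rotation_preserves_small_strain_eigenvalues(self, worked_pair, angle_deg):
        r = rotation_matrix(math.radians(angle_deg))
        rotated = worked_pair.transformed(r)
        base = np.sort(np.linalg.eigvalsh(element_strain(worked_pair, "centroid")[0].as_matrix()))
        rot = np.sort(np.linalg.eigvalsh(element_strain(rotated, "centroid")[0].as_matrix()))
        assert np.allclose(base, rot, atol=1e-10)

    @given(seed=st.integers(0, 5000))
    def test_co_rotation_random(self, seed):
        rng = np.random.default_rng(seed)
        quad = random_simple_quad(seed)
        pair = DeformationPair(quad, quad.transformed(np.diag([0.92, 1.40])))
        r = rotation_matrix(rng.uniform(-math.pi, math.pi))
        rotated = pair.transformed(r, rng.normal(0, 10, 2))
        base = np.sort(np.linalg.eigvalsh(element_strain(pair, "centroid")[0].as_matrix()))
        rot = np.sort(np.linalg.eigvalsh(element_strain(rotated, "centroid")[0].as_matrix()))
        assert np.allclose(base, rot, atol=1e-10)

    def test_deformed_only_rotation_invariance_split(self, worked_pair):
        """Rotating only the deformed configuration (rotation acquired during
        deformation) leaves green_lagrange and biot strains unchanged, while
        small strain is demonstrably not invariant (25 deg at 40% stretch)."""
        r = rotation_matrix(math.radians(25))
        rotated = worked_pair.transformed(r, which="deformed")
        for measure in ("green_lagrange", "biot"):
            a = element_strain(worked_pair, "centroid", measure)[0].as_matrix()
            b = element_strain(rotated, "centroid", measure)[0].as_matrix()
            assert np.allclose(a, b, atol=1e-10), measure
        small_a = element_strain(worked_pair, "centroid", "small")[0].as_matrix()
        small_b = element_strain(rotated, "centroid", "small")[0].as_matrix()
        assert np.linalg.norm(small_a - small_b) > 0.01

    def test_translation_and_uniform_scale(self, worked_pair):
        base = element_strain(worked_pair, "centroid")[0].as_matrix()
        shifted = worked_pair.transformed(translation=(123.4, -56.7))
        scaled = worked_pair.transformed(np.eye(2) * 0.037)
        assert np.allclose(element_strain(shifted, "centroid")[0].as_matrix(), base, atol=1e-10)
        assert np.allclose(element_strain(scaled, "centroid")[0].as_matrix(), base, atol=1e-10)


class TestMarkerQuadInvariants:
    def test_canonical_order_is_permutation_invariant(self):
        verts = [(0.0, 0.0), (4.0, 0.2), (4.3, 3.1), (-0.2, 2.9)]
        labels = ["a", "b", "c", "d"]
        base = MarkerQuad(verts, labels)
        for perm in [(1, 2, 3, 0), (3, 2, 1, 0), (2, 0, 3, 1)]:
            q = MarkerQuad([verts[i] for i in perm], [labels[i] for i in perm])
            assert np.allclose(q.vertices, base.vertices)
            assert q.labels == base.labels
        assert base.signed_area > 0

    def test_rejects_degenerate_input(self):
        with pytest.raises(InvalidQuadError):
            MarkerQuad([(0, 0), (0, 0), (1, 1), (0, 1)])  # coincident markers
        with pytest.raises(InvalidQuadError):
            MarkerQuad([(0, 0), (1, 0), (2, 0), (3, 0)])  # collinear
        with pytest.raises(InvalidQuadError):
            # bowtie stays self-intersecting under any cyclic/angular reordering
            MarkerQuad([(0, 0), (1, 1), (1, 0), (0, 1)], canonicalize=False)

    def test_label_mismatch_rejected(self):
        a = MarkerQuad(UNIT_SQUARE, ["a", "b", "c", "d"])
        b = MarkerQuad(UNIT_SQUARE, ["a", "b", "c", "e"])
        with pytest.raises(InvalidQuadError):
            DeformationPair(a, b)
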