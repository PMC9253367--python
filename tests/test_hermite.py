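"""Cubic Hermite basis, interpolation, arc lengths and scale factors."""

import numpy as np
import pytest

from loopkin.hermite import (
    arc_length,
    arc_length_1d,
    basis_functions,
    edge_arc_length,
    interpolate,
    interpolate_1d,
    surface_point,
    update_scale_factors,
)
from loopkin.fitting import build_template_tube
from loopkin.phantoms import PhantomSpec, true_mesh


class TestBasis:
    @pytest.mark.parametrize("xi,expected", [
        (0.0, (1.0, 0.0, 0.0, 0.0)),
        (1.0, (0.0, 1.0, 0.0, 0.0)),
        (0.5, (0.5, 0.5, 0.125, -0.125)),
    ])
    def test_values(self, xi, expected):
        assert basis_functions(xi) == pytest.approx(expected, abs=1e-15)

    def test_partition_of_unity(self):
        xi = np.linspace(0, 1, 101)
        p10, p20, _, _ = basis_functions(xi)
        assert np.max(np.abs(p10 + p20 - 1.0)) < 1e-12

    def test_domain_error(self):
        with pytest.raises(ValueError):
            basis_functions(1.2)
        with pytest.raises(ValueError):
            basis_functions(-0.1)


class TestInterpolation:
    def test_straight_segment_midpoint(self):
        # unit arc-length derivatives with scale factor = segment length
        assert interpolate_1d(0.0, 10.0, 1.0, 1.0, 10.0, 0.5) == pytest.approx(5.0)

    def test_corner_reproduces_node(self, template):
        elem = template.elements[3]
        for corner, (x1, x2) in zip(range(4), [(0, 0), (1, 0), (0, 1), (1, 1)]):
            for layer, x3 in ((0, 0.0), (1, 1.0)):
                nid = elem.layer_nodes(layer)[corner]
                pos = interpolate(template, 3, (x1, x2, x3))
                assert pos == pytest.approx(template.nodes[nid].x, abs=1e-10)

    def test_cubic_reproduction(self):
        # nodal values/derivatives sampled from a cubic polynomial in s
        S = 7.0
        coef = np.array([1.0, 2.0, -0.3, 0.01])

        def p(s):
            return coef @ np.array([1.0, s, s**2, s**3])

        def dp(s):
            return coef @ np.array([0.0, 1.0, 2 * s, 3 * s**2])

        xi = np.linspace(0, 1, 23)
        got = interpolate_1d(p(0.0), p(S), dp(0.0), dp(S), S, xi)
        want = np.array([p(x * S) for x in xi])
        assert np.max(np.abs(got - want)) < 1e-10


class TestArcLength:
    def test_straight_segment(self):
        assert arc_length_1d(np.zeros(3), np.array([10.0, 0, 0]),
                             np.array([1.0, 0, 0]), np.array([1.0, 0, 0]),
                             10.0) == pytest.approx(10.0, abs=1e-12)

    def test_degenerate_edge(self):
        z = np.zeros(3)
        assert arc_length_1d(z, z, z, z, 1.0) == pytest.approx(0.0)

    def test_quarter_circle(self):
        # Hermite approximation of a quarter circle of radius 2, with the
        # standard circle-approximating tangent magnitude 4 tan(theta/4) r
        u1, u2 = np.array([2.0, 0, 0]), np.array([0.0, 2.0, 0])
        d1, d2 = np.array([0.0, 1.0, 0]), np.array([-1.0, 0.0, 0])
        S = 4.0 * np.tan(np.pi / 8.0) * 2.0
        s_gauss = arc_length_1d(u1, u2, d1, d2, S)
        # dense polyline oracle over the same Hermite curve
        t = np.linspace(0, 1, 20001)
        pts = interpolate_1d(u1, u2, d1, d2, S, t)
        s_poly = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        assert s_gauss == pytest.approx(s_poly, abs=1e-6)
        assert abs(s_gauss - np.pi) < 1e-2

    def test_rigid_invariance(self, template):
        before = arc_length(template, 5, 0, layer=1, side=0)
        rot = np.array([[0.0, -1.0, 0], [1.0, 0.0, 0], [0, 0, 1.0]])
        moved = template.copy()
        for nd in moved.nodes:
            nd.x = rot @ nd.x + np.array([3.0, -1.0, 2.0])
            nd.d1, nd.d2, nd.d12 = rot @ nd.d1, rot @ nd.d2, rot @ nd.d12
        after = arc_length(moved, 5, 0, layer=1, side=0)
        assert after == pytest.approx(before, rel=1e-12)


class TestScaleFactors:
    def test_straight_tube_longitudinal(self, template):
        # longitudinal edges are straight: S2 = inter-node Euclidean distance
        n_per = template.n_per_layer
        d = np.linalg.norm(template.nodes[n_per + 4].x - template.nodes[n_per].x)
        assert template.scale_factors[n_per, 1] == pytest.approx(d, rel=1e-9)

    def test_uniform_scaling_doubles_factors(self, template):
        scaled = template.copy()
        for nd in scaled.nodes:
            nd.x = 2.0 * nd.x
        update_scale_factors(scaled)
        assert np.allclose(scaled.scale_factors, 2.0 * template.scale_factors,
                           rtol=1e-8)

    def test_unit_arc_length_derivatives_on_bent_tube(self):
        mesh = true_mesh(PhantomSpec(seed=0), 3)
        for nd in mesh.nodes:
            assert np.linalg.norm(nd.d1) == pytest.approx(1.0, abs=1e-6)
            assert np.linalg.norm(nd.d2) == pytest.approx(1.0, abs=1e-6)
        # fixed point: recomputing the arc lengths changes nothing
        before = mesh.scale_factors.copy()
        update_scale_factors(mesh)
        assert np.allclose(mesh.scale_factors, before, rtol=1e-6)


class TestContinuity:
    def test_c1_across_shared_edges(self):
        # adjacent elements agree on position and arc-length first derivative
        mesh = true_mesh(PhantomSpec(seed=0), 2)
        n_circ, _ = mesh.tube_shape
        e_left, e_right = 0, 1  # share the xi1=1 edge of e_left
        for x2 in np.linspace(0.05, 0.95, 7):
            pL = surface_point(mesh, e_left, 1.0, x2)
            pR = surface_point(mesh, e_right, 0.0, x2)
            assert pL == pytest.approx(pR, abs=1e-8)
            # transverse (xi1) arc-length derivative across the edge
            nid = mesh.elements[e_left].layer_nodes(1)[1]
            tL = surface_point(mesh, e_left, 1.0, x2, d1=1)
            tR = surface_point(mesh, e_right, 0.0, x2, d1=1)
            SL = mesh.scale_factors[nid, 0]
            assert tL / SL == pytest.approx(tR / SL, abs=1e-8)
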