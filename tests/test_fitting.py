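"""Template construction, projection, regularized fitting, refinement."""

import numpy as np
import pytest

from loopkin.fitting import (
    FitConfig,
    PointCloud,
    build_template_tube,
    compute_rms,
    fit_mesh,
    project_points,
    refine_and_bin,
)
from loopkin.hermite import surface_normal, surface_params, surface_weights, _gauss01
from loopkin.phantoms import (
    PhantomSpec,
    fit_time_point,
    landmark_points,
    sample_point_cloud,
)


def _surface_cloud(mesh, n_per_element=60, seed=0):
    rng = np.random.default_rng(seed)
    pts = []
    for e in range(mesh.n_elements):
        P = surface_params(mesh, e, 1)
        xi = rng.random((n_per_element, 2))
        pts.append(surface_weights(xi[:, 0], xi[:, 1]) @ P)
    return PointCloud(np.vstack(pts))


class TestTemplate:
    def test_default_counts(self, template):
        assert template.n_nodes == 56
        assert template.n_elements == 24
        assert template.n_per_layer == 28  # 28 internal + 28 external

    def test_counting_formula(self):
        m = build_template_tube(n_circ=4, n_long=2, radius=50, length=100)
        assert m.n_elements == 8
        assert m.n_nodes == 24

    def test_invalid_dims(self):
        with pytest.raises(ValueError):
            build_template_tube(n_circ=2)
        with pytest.raises(ValueError):
            build_template_tube(n_long=0)


class TestProjection:
    def test_point_on_surface(self, template):
        pt = surface_weights(0.3, 0.7) @ surface_params(template, 5, 1)
        proj = project_points(PointCloud(pt[None]), template)
        assert proj.distance[0] < 1e-8
        assert proj.element_id[0] == 5

    def test_normal_offset_distance(self, template):
        base = surface_weights(0.4, 0.5) @ surface_params(template, 2, 1)
        n = surface_normal(template, 2, 0.4, 0.5)
        proj = project_points(PointCloud((base + 2.0 * n)[None]), template)
        assert proj.distance[0] == pytest.approx(2.0, abs=1e-3)

    def test_tie_break_lowest_element(self, template):
        # a point on the shared edge of elements 0 and 1 is equidistant
        elem0 = template.elements[0]
        nid = elem0.layer_nodes(1)[1]  # corner shared with element 1
        pt = surface_weights(1.0, 0.5) @ surface_params(template, 0, 1)
        proj = project_points(PointCloud(pt[None]), template)
        assert proj.element_id[0] == 0

    def test_empty_cloud_error(self, template):
        with pytest.raises(ValueError):
            PointCloud(np.empty((0, 3)))


class TestRMS:
    def test_values(self):
        assert compute_rms([0.0, 0.0, 0.0]) == 0.0
        assert compute_rms([3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
        assert compute_rms([2.7]) == pytest.approx(2.7)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            compute_rms([])


class TestFit:
    def test_self_fit_machine_zero(self, template):
        cloud = _surface_cloud(template)
        res = fit_mesh(cloud, template,
                       FitConfig(alpha=0.0, beta=0.0, max_iters=3,
                                 rms_tol=1e-9))
        assert res.rms < 1e-6

    def test_rms_never_worse_than_start(self, full_spec):
        cloud = sample_point_cloud(full_spec, 2, n=2000, seed=5)
        res = fit_time_point(full_spec, 2, cloud=cloud,
                             cfg=FitConfig(max_iters=5))
        assert res.rms_history[-1] <= res.rms_history[0]

    def test_phantom_bent_tube_under_3um(self, full_spec):
        # the printed fitting-accuracy bound for subject hearts
        cloud = sample_point_cloud(full_spec, 3, n=5000, noise_sigma=0.5,
                                   seed=42)
        res = fit_time_point(full_spec, 3, cloud=cloud,
                             cfg=FitConfig(max_iters=8))
        assert res.rms < 3.0

    def test_rigid_equivariance(self, full_spec):
        from loopkin.hermite import update_scale_factors

        cloud = sample_point_cloud(full_spec, 1, n=1500, seed=3)
        res = fit_time_point(full_spec, 1, cloud=cloud,
                             cfg=FitConfig(max_iters=3))
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        shift = np.array([20.0, -10.0, 5.0])
        moved_cloud = PointCloud(cloud.points @ rot.T + shift)
        tmpl = res.mesh  # any template; rotate it jointly with the cloud
        moved_tmpl = tmpl.copy()
        for nd in moved_tmpl.nodes:
            nd.x = rot @ nd.x + shift
            nd.d1, nd.d2, nd.d12 = rot @ nd.d1, rot @ nd.d2, rot @ nd.d12
        update_scale_factors(moved_tmpl)
        r1 = fit_mesh(cloud, tmpl, FitConfig(max_iters=2))
        r2 = fit_mesh(moved_cloud, moved_tmpl, FitConfig(max_iters=2))
        assert r2.rms == pytest.approx(r1.rms, rel=1e-4, abs=1e-6)
        for n1, n2 in zip(r1.mesh.nodes, r2.mesh.nodes):
            assert rot @ n1.x + shift == pytest.approx(n2.x, abs=1e-5)

    def test_more_beta_smoother_surface(self, full_spec):
        cloud = sample_point_cloud(full_spec, 2, n=2500, noise_sigma=1.0,
                                   seed=9)

        def curvature_energy(mesh):
            xg, wg = _gauss01(4)
            q1, q2 = np.meshgrid(xg, xg, indexing="ij")
            w = np.outer(wg, wg).ravel()
            total = 0.0
            for e in range(mesh.n_elements):
                P = surface_params(mesh, e, 1)
                for (d1, d2), coef in (((2, 0), 1.0), ((0, 2), 1.0),
                                       ((1, 1), 2.0)):
                    W = surface_weights(q1.ravel(), q2.ravel(), d1, d2)
                    total += coef * np.sum(w * np.sum((W @ P) ** 2, axis=1))
            return total

        r1 = fit_time_point(full_spec, 2, cloud=cloud,
                            cfg=FitConfig(beta=1e-4, max_iters=4))
        r2 = fit_time_point(full_spec, 2, cloud=cloud,
                            cfg=FitConfig(beta=2e-4, max_iters=4))
        assert curvature_energy(r2.mesh) <= curvature_energy(r1.mesh) * (1 + 1e-6)


class TestRefineAndBin:
    def test_counts(self, template):
        refined, bins = refine_and_bin(template)
        assert refined.n_elements == 96
        assert len(bins) == 600

    def test_middle_bin_center(self, template):
        _, bins = refine_and_bin(template)
        assert bins.center(7, 2, 2) == (0.5, 0.5)

    def test_refined_surface_matches_parent(self, template):
        refined, bins = refine_and_bin(template)
        for e in (0, 13):
            for x1, x2 in ((0.2, 0.3), (0.8, 0.6)):
                parent = surface_weights(x1, x2) @ surface_params(template, e, 1)
                re, r1, r2 = bins.to_refined(e, x1, x2)
                child = surface_weights(r1, r2) @ surface_params(refined, re, 1)
                assert child == pytest.approx(parent, abs=0.5)
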