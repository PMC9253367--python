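"""Phantom generator: determinism, ground truths, end-to-end recovery."""

import numpy as np
import pandas as pd
import pytest

from loopkin.fitting import FitConfig
from loopkin.kinematics import deformation_gradient_field, records_to_frame
from loopkin.morphometry import LabeledVolume, cell_features
from loopkin.phantoms import (
    PhantomSpec,
    bin_material_points,
    cell_table_at_time,
    fit_time_point,
    generate_cells,
    generate_series,
    inverse_map,
    map_material,
    rasterize,
    sample_point_cloud,
    true_jacobian,
    true_mesh,
)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        spec = PhantomSpec.desk(seed=21)
        s1, c1 = generate_series(spec)
        s2, c2 = generate_series(spec)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.point_cloud.points, b.point_cloud.points)
            pd.testing.assert_frame_equal(a.cell_table, b.cell_table)
        pd.testing.assert_frame_equal(c1, c2)

    def test_rasterize_deterministic(self, desk_spec):
        cells = generate_cells(desk_spec)
        l1, m1, o1 = rasterize(desk_spec, cells, 0)
        l2, m2, o2 = rasterize(desk_spec, cells, 0)
        assert np.array_equal(l1, l2) and np.array_equal(m1, m2)


class TestMapGeometry:
    def test_inverse_map_roundtrip(self, full_spec, rng):
        m = np.column_stack([
            rng.uniform(0, 2 * np.pi, 200),
            rng.uniform(0, full_spec.length, 200),
            rng.uniform(full_spec.r_inner, full_spec.radius, 200)])
        for t in range(full_spec.n_time_points):
            x = map_material(full_spec, t, m)
            back = inverse_map(full_spec, t, x)
            assert back == pytest.approx(m, abs=1e-8)

    def test_zero_bend_zero_twist_gives_identity_F(self):
        spec = PhantomSpec(seed=1, bend_angles=(0.0, 0.0),
                           twist_angles=(0.0, 0.0), growth_scales=(1.0, 1.0))
        df = records_to_frame(deformation_gradient_field(
            true_mesh(spec, 0), true_mesh(spec, 1)))
        F = df[[f"F{a}{b}" for a in (1, 2, 3) for b in (1, 2, 3)]].to_numpy()
        assert np.abs(F - np.eye(3).ravel()).max() < 1e-6


class TestPointCloud:
    def test_noiseless_points_on_analytic_surface(self, full_spec):
        cloud = sample_point_cloud(full_spec, 2, n=500, noise_sigma=0.0,
                                   seed=4)
        m = inverse_map(full_spec, 2, cloud.points)
        r_out = full_spec.radius * full_spec.growth_scales[2]
        assert m[:, 2] * full_spec.growth_scales[2] == pytest.approx(
            r_out, abs=1e-9)

    def test_noise_offset_half_normal_mean(self, full_spec):
        sigma = 0.5
        cloud = sample_point_cloud(full_spec, 0, n=5000, noise_sigma=sigma,
                                   seed=4)
        m = inverse_map(full_spec, 0, cloud.points)
        radial = np.abs(m[:, 2] * full_spec.growth_scales[0]
                        - full_spec.radius * full_spec.growth_scales[0])
        assert radial.mean() == pytest.approx(sigma * np.sqrt(2 / np.pi),
                                              abs=0.02)

    def test_minimum_count(self, full_spec):
        with pytest.raises(ValueError):
            sample_point_cloud(full_spec, 0, n=50)


class TestCells:
    def test_volume_and_anisotropy_ranges(self, desk_spec):
        cells = generate_cells(desk_spec)
        assert len(cells) > 0.6 * desk_spec.n_cells
        assert cells["volume"].between(*desk_spec.cell_volume_range).all()
        assert cells["anisotropy"].between(*desk_spec.anisotropy_range).all()

    def test_morphometry_recovers_generating_cells(self, desk_spec):
        cells = generate_cells(desk_spec)
        labels, mask, origin = rasterize(desk_spec, cells, 0)
        lv = LabeledVolume(labels, desk_spec.voxel_size, origin)
        feats = cell_features(lv)
        truth = cell_table_at_time(desk_spec, cells, 0)
        merged = feats.merge(truth, on="label", suffixes=("", "_true"))
        assert len(merged) > 0.8 * len(truth)
        # volume distribution median within 5%
        med_ratio = merged["volume_um3"].median() / \
            merged["volume_um3_true"].median()
        assert med_ratio == pytest.approx(1.0, abs=0.05)
        # principal direction within 5 degrees for elongated cells
        elong = merged[merged["anisotropy_true"] > 0.5]
        v = elong[["vec1x", "vec1y", "vec1z"]].to_numpy()
        vt = elong[["vec1x_true", "vec1y_true", "vec1z_true"]].to_numpy()
        cos = np.abs(np.einsum("ij,ij->i", v, vt))
        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert np.median(ang) < 5.0


class TestEndToEndRecovery:
    def test_uniform_scaling_recovers_cubed_jacobian(self):
        # growth 1.1 between time points -> J = 1.331 everywhere
        spec = PhantomSpec(seed=3, bend_angles=(30.0, 30.0),
                           twist_angles=(0.0, 0.0), growth_scales=(1.0, 1.1),
                           n_cloud_points=20000)
        meshes = [fit_time_point(spec, t, cfg=FitConfig(max_iters=6)).mesh
                  for t in (0, 1)]
        df = records_to_frame(deformation_gradient_field(meshes[0], meshes[1]))
        assert df["J"].to_numpy() == pytest.approx(1.331, rel=0.02)

    def test_series_jacobian_median_error_under_5pct(self, full_spec):
        meshes = [fit_time_point(full_spec, t, cfg=FitConfig(max_iters=6)).mesh
                  for t in (0, 1)]
        df = records_to_frame(deformation_gradient_field(meshes[0], meshes[1]))
        j_true = true_jacobian(full_spec, 0, 1, bin_material_points(full_spec))
        rel = np.abs(df["J"].to_numpy() - j_true) / j_true
        assert np.median(rel) < 0.05
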