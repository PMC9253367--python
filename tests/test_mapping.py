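"""Rigid alignment, bin aggregation, field fitting, neighbor variance."""

import numpy as np
import pandas as pd
import pytest

from loopkin.fitting import FitConfig, refine_and_bin
from loopkin.hermite import surface_params, surface_weights
from loopkin.mapping import (
    bin_deltas,
    fit_feature_field,
    map_cells_to_bins,
    neighbor_variance,
    rigid_align,
)


class TestRigidAlign:
    def test_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        tr = rigid_align(pts, pts)
        assert tr.rotation == pytest.approx(np.eye(3), abs=1e-12)
        assert tr.translation == pytest.approx(np.zeros(3), abs=1e-12)

    def test_recovers_known_transform(self, rng):
        src = rng.normal(size=(5, 3))
        th = np.deg2rad(30)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        t = np.array([5.0, -2.0, 1.0])
        tr = rigid_align(src, src @ R.T + t)
        assert tr.rotation == pytest.approx(R, abs=1e-8)
        assert tr.translation == pytest.approx(t, abs=1e-8)

    def test_no_scaling_contract(self, rng):
        src = rng.normal(size=(5, 3))
        tr = rigid_align(src, 1.5 * src)
        assert tr.residual > 0
        assert tr.rotation @ tr.rotation.T == pytest.approx(np.eye(3),
                                                            abs=1e-10)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)

    def test_two_point_alignment(self):
        src = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        dst = np.array([[2.0, 1, 0], [2.0, 2, 0]])
        tr = rigid_align(src, dst)
        assert tr.apply(src) == pytest.approx(dst, abs=1e-10)

    def test_degenerate_collinear(self):
        src = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError):
            rigid_align(src, src + 1.0)


def _cell_row(label, pos, volume=10.0, aniso=0.5):
    return {
        "label": label, "cx": pos[0], "cy": pos[1], "cz": pos[2],
        "volume_um3": volume, "ev1": 2.0, "ev2": 1.0, "ev3": 1.0,
        "vec1x": 1.0, "vec1y": 0.0, "vec1z": 0.0,
        "vec2x": 0.0, "vec2y": 1.0, "vec2z": 0.0,
        "vec3x": 0.0, "vec3y": 0.0, "vec3z": 1.0,
        "anisotropy": aniso,
    }


class TestMapCellsToBins:
    def test_cell_at_bin_center(self, template):
        pos = surface_weights(0.5, 0.5) @ surface_params(template, 7, 1)
        cells = pd.DataFrame([_cell_row(1, pos)])
        table, unassigned = map_cells_to_bins(cells, template)
        row = table[(table.element == 7) & (table.i == 2) & (table.j == 2)]
        assert int(row["N_cell"].iloc[0]) == 1
        assert len(unassigned) == 0

    def test_mean_volume(self, template):
        pos = surface_weights(0.3, 0.3) @ surface_params(template, 2, 1)
        cells = pd.DataFrame([_cell_row(1, pos, volume=2.0),
                              _cell_row(2, pos, volume=4.0)])
        table, _ = map_cells_to_bins(cells, template)
        row = table[(table.element == 2) & (table.i == 1) & (table.j == 1)]
        assert row["V_cell_mean"].iloc[0] == pytest.approx(3.0)

    def test_conservation_and_invariants(self, desk_spec):
        from loopkin.morphometry import LabeledVolume
        from loopkin.phantoms import generate_cells, cell_table_at_time, \
            rasterize, true_mesh

        cells_m = generate_cells(desk_spec)
        cells = cell_table_at_time(desk_spec, cells_m, 0)
        mesh = true_mesh(desk_spec, 0)
        labels, mask, origin = rasterize(desk_spec, cells_m, 0)
        mv = LabeledVolume(mask.astype(np.uint8), desk_spec.voxel_size, origin)
        table, unassigned = map_cells_to_bins(cells, mesh, mask=mv,
                                              tissue_sample_step=3)
        assert table["N_cell"].sum() + len(unassigned) == len(cells)
        filled = table[table["N_cell"] > 0].dropna(subset=["V_tissue"])
        assert len(filled) > 50
        # stated bin identities: V_ICS = V_tissue - sum(V_cell), rho = N/V_t
        v_sum = filled["N_cell"] * filled["V_cell_mean"]
        assert filled["V_ICS"].to_numpy() == pytest.approx(
            (filled["V_tissue"] - v_sum).to_numpy())
        assert filled["rho"].to_numpy() == pytest.approx(
            (filled["N_cell"] / filled["V_tissue"]).to_numpy())

    def test_ordering_invariance(self, template, rng):
        pts = [surface_weights(u, v) @ surface_params(template, e, 1)
               for e, u, v in zip(rng.integers(0, 24, 30),
                                  rng.random(30), rng.random(30))]
        cells = pd.DataFrame([_cell_row(i + 1, p, volume=float(i + 1))
                              for i, p in enumerate(pts)])
        t1, _ = map_cells_to_bins(cells, template)
        t2, _ = map_cells_to_bins(cells.iloc[::-1].reset_index(drop=True),
                                  template)
        a = t1.sort_values(["element", "i", "j"]).fillna(0)
        b = t2.sort_values(["element", "i", "j"]).fillna(0)
        assert np.allclose(a["N_cell"], b["N_cell"])
        assert np.allclose(a["V_cell_mean"], b["V_cell_mean"])


class TestFieldFit:
    def test_constant_field(self, template):
        rows = [(e, u, v, 3.25) for e in range(24)
                for u in (0.2, 0.6) for v in (0.3, 0.8)]
        df = pd.DataFrame(rows, columns=["element", "xi1", "xi2", "value"])
        field = fit_feature_field(df, template, FitConfig(alpha=1e-4, beta=1e-5))
        for e in (0, 11, 23):
            assert field.evaluate(e, 0.4, 0.7) == pytest.approx(3.25, abs=1e-6)

    def test_linear_gradient_recovery(self, template):
        def truth(e, x2):
            return ((e // 4) + x2) / 6.0  # longitudinal fraction

        rows = [(e, u, v, truth(e, v)) for e in range(24)
                for u in (0.17, 0.5, 0.83) for v in (0.17, 0.5, 0.83)]
        df = pd.DataFrame(rows, columns=["element", "xi1", "xi2", "value"])
        field = fit_feature_field(df, template, FitConfig(alpha=1e-4, beta=1e-5))
        errs = [abs(field.evaluate(e, u, v) - truth(e, v))
                for e in range(24) for u in (0.3, 0.7) for v in (0.25, 0.75)]
        assert max(errs) < 0.05  # < 5% of the unit range

    def test_stronger_alpha_reduces_variation(self, template, rng):
        rows = [(e, u, v, float(rng.normal())) for e in range(24)
                for u in (0.25, 0.75) for v in (0.25, 0.75)]
        df = pd.DataFrame(rows, columns=["element", "xi1", "xi2", "value"])
        refined = refine_and_bin(template)

        def variation(field):
            tot = 0.0
            for e in range(24):
                for u in np.linspace(0.1, 0.9, 5):
                    for v in np.linspace(0.1, 0.9, 5):
                        re, r1, r2 = field.bin_index.to_refined(e, u, v)
                        w1 = surface_weights(r1, r2, d1=1)
                        w2 = surface_weights(r1, r2, d2=1)
                        # parameter-space gradient magnitude of the field
                        elem = field.mesh.elements[re]
                        idx = []
                        n_per = field.mesh.n_per_layer
                        for nid in elem.layer_nodes(1):
                            s = nid - n_per
                            idx.extend(range(4 * s, 4 * s + 4))
                        p = field.params[idx, 0]
                        tot += np.hypot(w1 @ p, w2 @ p)
            return tot

        f1 = fit_feature_field(df, template, FitConfig(alpha=1e-4, beta=1e-5),
                               refined=refined)
        f2 = fit_feature_field(df, template, FitConfig(alpha=1e-3, beta=1e-5),
                               refined=refined)
        assert variation(f2) <= variation(f1) * (1 + 1e-9)

    def test_empty_data_error(self, template):
        with pytest.raises(ValueError):
            fit_feature_field(pd.DataFrame(columns=["element", "xi1", "xi2",
                                                    "value"]), template)


class TestNeighborVariance:
    def test_constant_feature(self):
        cells = pd.DataFrame({"cx": np.arange(12.0), "cy": 0.0, "cz": 0.0,
                              "f": 5.0})
        assert neighbor_variance(cells, "f") == pytest.approx(0.0)

    def test_one_to_ten(self):
        cells = pd.DataFrame({"cx": np.arange(10.0), "cy": 0.0, "cz": 0.0,
                              "f": np.arange(1.0, 11.0)})
        # population variance of 1..10 over cell + 9 neighbors
        assert neighbor_variance(cells, "f") == pytest.approx(8.25)

    def test_quadratic_scaling(self, rng):
        cells = pd.DataFrame({"cx": rng.random(30), "cy": rng.random(30),
                              "cz": rng.random(30), "f": rng.random(30)})
        v1 = neighbor_variance(cells, "f")
        cells["f"] *= 3.0
        assert neighbor_variance(cells, "f") == pytest.approx(9.0 * v1)

    def test_too_few_cells(self):
        cells = pd.DataFrame({"cx": np.arange(5.0), "cy": 0.0, "cz": 0.0,
                              "f": 1.0})
        with pytest.raises(ValueError):
            neighbor_variance(cells, "f", k=9)


def test_bin_deltas_arithmetic(template):
    base = pd.DataFrame({
        "element": [0, 0], "i": [1, 2], "j": [1, 2],
        "region": ["ventral", "dorsal"], "time": [0, 0],
        "N_cell": [4, 6], "V_cell_mean": [10.0, 12.0],
        "V_tissue": [100.0, 120.0], "V_ICS": [60.0, 48.0],
        "rho": [0.04, 0.05], "anisotropy_mean": [0.5, 0.6],
        "evec_x": 1.0, "evec_y": 0.0, "evec_z": 0.0, "eval1": 2.0,
    })
    later = base.copy()
    later["time"] = 1
    later["N_cell"] = [6, 7]
    later["V_tissue"] = [130.0, 150.0]
    d = bin_deltas(base, later)
    assert list(d["dN_cell"]) == [2, 1]
    assert list(d["dV_tissue"]) == [30.0, 30.0]
    assert list(d["Region"]) == ["ventral", "dorsal"]
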