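"""End-to-end pipeline driver: simulate, fit, extract, map, kinematics, stats.

Orchestrates the full phantom-based analysis so the whole chain is exercised
by one command.  Every stage reads only files produced by earlier stages,
writes its outputs under the run directory, and is recorded (with content
hashes) in a manifest; all randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .fitting import FitConfig, PointCloud
from .kinematics import deformation_gradient_field, records_to_frame
from .mapping import bin_deltas, map_cells_to_bins, neighbor_variance
from .morphometry import LabeledVolume, cell_features, label_and_separate
from .phantoms import PhantomSpec, fit_time_point, generate_series, rasterize
from .stats import GlmSpec, stepwise_glm

__all__ = ["PipelineConfig", "run_pipeline", "default_region_map"]

log = logging.getLogger("loopkin.pipeline")

STAGES = ["simulate", "fit", "extract", "map", "kinematics", "variance",
          "stats"]


@dataclass
class PipelineConfig:
    """Run directory, seed and per-stage knobs; loadable from YAML."""

    outdir: str = "loopkin_run"
    seed: int = 0
    phantom: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    tissue_sample_step: int = 2
    use_voxels: bool = True
    n_circ: int = 4
    n_long: int = 6
    resume: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def spec(self) -> PhantomSpec:
        # reduced-scale phantom by default: the voxel stages need a grid a
        # desk machine can hold
        return PhantomSpec.desk(seed=self.seed, **self.phantom)


def default_region_map(n_circ: int = 4, n_long: int = 6) -> dict:
    """Element -> region lookup for the standard four-region segmentation.

    The outer-curvature quadrant is ventral, the inner-curvature quadrant
    dorsal, the two remaining quadrants lateral, and the cranial element ring
    is the outflow tract (OFT).
    """
    regions = {}
    for e in range(n_circ * n_long):
        c, jrow = e % n_circ, e // n_circ
        if jrow == n_long - 1:
            regions[e] = "OFT"
        elif c == 0:
            regions[e] = "dorsal"
        elif c == n_circ // 2:
            regions[e] = "ventral"
        else:
            regions[e] = "lateral"
    return regions


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    With ``cfg.resume`` a stage whose outputs already exist is skipped.  A
    stage failure raises with the stage named.  The manifest lists every
    artifact with its sha256, so re-runs with the same seed are verifiable.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cfg.spec()
    nT = spec.n_time_points
    regions = default_region_map(cfg.n_circ, cfg.n_long)
    manifest = {"seed": cfg.seed, "stages": {}, "artifacts": {}}

    def record(stage, paths):
        manifest["stages"][stage] = [str(p.relative_to(out)) for p in paths]
        for p in paths:
            manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)

    def outputs_exist(paths):
        return all(p.exists() for p in paths)

    stage_outputs = {
        "simulate": [out / f"cloud_t{t}.csv" for t in range(nT)]
        + [out / "cells_true.csv"],
        "fit": [out / f"fitted_t{t}.json" for t in range(nT)]
        + [out / "rms.csv"],
        "extract": [out / f"cells_t{t}.csv" for t in range(nT)],
        "map": [out / f"bins_t{t}.csv" for t in range(nT)],
        "kinematics": [out / f"deform_t{t}{t+1}.csv" for t in range(nT - 1)],
        "variance": [out / f"variance_t{t}.csv" for t in range(nT)],
        "stats": [out / "glm_model.json", out / "deltas.csv"],
    }

    for stage in STAGES:
        paths = stage_outputs[stage]
        if cfg.resume and outputs_exist(paths):
            log.info("stage %s: outputs present, skipped (resume)", stage)
            record(stage, paths)
            continue
        log.info("stage %s: running", stage)
        try:
            _run_stage(stage, cfg, spec, regions, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
        record(stage, paths)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True) + "\n")
    return out


def _run_stage(stage, cfg: PipelineConfig, spec: PhantomSpec, regions, out: Path):
    nT = spec.n_time_points

    if stage == "simulate":
        series, cells = generate_series(spec, cfg.n_circ, cfg.n_long)
        for tp in series:
            tp.point_cloud.to_csv(out / f"cloud_t{tp.t}.csv")
            lio.save_mesh(tp.mesh, out / f"true_t{tp.t}.json")
            np.savetxt(out / f"landmarks_t{tp.t}.csv", tp.landmarks,
                       delimiter=",", header="x,y,z", comments="")
            tp.cell_table.to_csv(out / f"cells_true_t{tp.t}.csv", index=False)
        cells.to_csv(out / "cells_true.csv", index=False)
        return

    if stage == "fit":
        rows = []
        for t in range(nT):
            cloud = PointCloud.from_csv(out / f"cloud_t{t}.csv")
            res = fit_time_point(spec, t, cloud=cloud,
                                 cfg=FitConfig(**cfg.fit),
                                 n_circ=cfg.n_circ, n_long=cfg.n_long)
            lio.save_mesh(res.mesh, out / f"fitted_t{t}.json")
            for it, rms in enumerate(res.rms_history):
                rows.append((t, it, rms))
        pd.DataFrame(rows, columns=["time", "iteration", "rms"]).to_csv(
            out / "rms.csv", index=False)
        return

    if stage == "extract":
        _, cells = generate_series(spec, cfg.n_circ, cfg.n_long)
        for t in range(nT):
            if cfg.use_voxels:
                labels, mask, origin = rasterize(spec, cells, t)
                lio.save_volume(labels, out / f"labels_t{t}.tif")
                lio.save_volume(mask.astype(np.uint8), out / f"myo_t{t}.tif")
                np.savetxt(out / f"origin_t{t}.csv", origin[None],
                           delimiter=",", header="x,y,z", comments="")
                lv = LabeledVolume(labels, spec.voxel_size, origin)
                feats = cell_features(lv)
            else:
                feats = pd.read_csv(out / f"cells_true_t{t}.csv")
            feats.to_csv(out / f"cells_t{t}.csv", index=False)
        return

    if stage == "map":
        for t in range(nT):
            cells = pd.read_csv(out / f"cells_t{t}.csv")
            mesh = lio.load_mesh(out / f"fitted_t{t}.json")
            mask = None
            if cfg.use_voxels:
                vox = lio.load_volume(out / f"myo_t{t}.tif")
                origin = np.loadtxt(out / f"origin_t{t}.csv", delimiter=",",
                                    skiprows=1)
                mask = LabeledVolume(vox, spec.voxel_size, origin)
            bins, unassigned = map_cells_to_bins(
                cells, mesh, mask=mask, regions=regions, time=t,
                tissue_sample_step=cfg.tissue_sample_step)
            bins.to_csv(out / f"bins_t{t}.csv", index=False)
        return

    if stage == "kinematics":
        meshes = [lio.load_mesh(out / f"fitted_t{t}.json") for t in range(nT)]
        for t in range(nT - 1):
            recs = deformation_gradient_field(meshes[t], meshes[t + 1])
            records_to_frame(recs).to_csv(out / f"deform_t{t}{t+1}.csv",
                                          index=False)
        return

    if stage == "variance":
        for t in range(nT):
            cells = pd.read_csv(out / f"cells_t{t}.csv")
            var = neighbor_variance(cells, "volume_um3", k=9)
            pd.DataFrame({"label": cells["label"],
                          "volume_variance": var}).to_csv(
                out / f"variance_t{t}.csv", index=False)
        return

    if stage == "stats":
        deltas = []
        for t in range(nT - 1):
            b0 = pd.read_csv(out / f"bins_t{t}.csv")
            b1 = pd.read_csv(out / f"bins_t{t+1}.csv")
            d = pd.read_csv(out / f"deform_t{t}{t+1}.csv")
            deltas.append(bin_deltas(b0, b1, d))
        table = pd.concat(deltas, ignore_index=True).dropna()
        table.to_csv(out / "deltas.csv", index=False)
        result = stepwise_glm(table, GlmSpec())
        model = {
            "formula": result.formula,
            "terms": [list(t) if isinstance(t, tuple) else t
                      for t in result.terms],
            "aic_trace": result.aic_trace,
            "r_squared": result.rsquared,
            "coefficients": {k: float(v)
                             for k, v in result.params.items()},
        }
        (out / "glm_model.json").write_text(json.dumps(model, indent=1) + "\n")
        return

    raise ValueError(f"unknown stage {stage!r}")
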