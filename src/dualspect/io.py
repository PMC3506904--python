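"""Readers, writers and the end-to-end pipeline runner.

Volumes travel as NIfTI (.nii.gz, float32, voxel size in the header, with a
companion ``*.labels.nii.gz`` for material labels); projection sets as a
NIfTI stack (bin-x, bin-y, view) plus a JSON sidecar holding the
acquisition geometry and energy window.  Specs and run configurations are
YAML.  Every artifact carries enough sidecar metadata to re-run its
producing stage exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .containers import ActivityVolume, AttenuationMap, ProjectionSet
from .mcscatter import McConfig
from .phantom import (StudySpec, build_cardiac_phantom,
                      cardiac_phantom_spec, simulate_study)
from .projector import CollimatorModel
from .reconstruct import ReconConfig, osem, reconstruct_dual
from .analysis import evaluate_contrast

__all__ = [
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
    "RunConfig",
    "run_pipeline",
]


def _affine(voxel_mm: float) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


def write_volume(path, volume) -> Path:
    """Write an activity volume or attenuation map as NIfTI."""
    path = Path(path)
    if isinstance(volume, ActivityVolume):
        data, voxel = volume.values, volume.voxel_mm
    elif isinstance(volume, AttenuationMap):
        data, voxel = volume.mu, volume.voxel_mm
        if volume.labels is not None:
            stem = path.name.split(".")[0]
            lab_path = path.with_name(stem + ".labels.nii.gz")
            nib.save(nib.Nifti1Image(np.asarray(volume.labels, dtype=np.int16),
                                     _affine(voxel)), lab_path)
            path.with_name(stem + ".materials.json").write_text(json.dumps(
                {"materials": list(volume.materials),
                 "reference_kev": volume.reference_kev}))
    else:
        raise TypeError(f"cannot write {type(volume).__name__}")
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), _affine(voxel)), path)
    return path


def read_volume(path, kind: str = "activity"):
    """Read a NIfTI volume back as an ActivityVolume or AttenuationMap."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a 3-D volume, got {data.ndim} axes")
    voxel = float(img.header.get_zooms()[0])
    if kind == "activity":
        return ActivityVolume(data, voxel)
    if kind == "attenuation":
        labels = materials = None
        ref = 140.0
        stem = path.name.split(".")[0]
        lab_path = path.with_name(stem + ".labels.nii.gz")
        if lab_path.exists():
            labels = np.asarray(nib.load(lab_path).dataobj, dtype=np.int16)
            meta_path = path.with_name(stem + ".materials.json")
            if meta_path.exists():
                meta = json.loads(meta_path.read_text())
                materials = tuple(meta.get("materials", ()))
                ref = float(meta.get("reference_kev", 140.0))
        return AttenuationMap(data, voxel, ref, labels=labels,
                              materials=materials or ())
    raise ValueError("kind must be 'activity' or 'attenuation'")


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name.split(".")[0] + ".json")


def write_projections(path, projections: ProjectionSet) -> Path:
    path = Path(path)
    stack = np.transpose(projections.data, (1, 2, 0))  # (u, z, view) on disk
    nib.save(nib.Nifti1Image(stack, _affine(projections.pixel_mm)), path)
    sidecar = {
        "angles_deg": list(map(float, projections.angles_deg)),
        "orbit_radius_mm": projections.orbit_radius_mm,
        "pixel_mm": projections.pixel_mm,
        "window_center_keV": projections.window_center_kev,
        "window_width_pct": (None if projections.window_width_frac is None
                             else 100.0 * projections.window_width_frac),
        "total_counts": projections.total(),
        "meta": {k: v for k, v in projections.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_projections(path) -> ProjectionSet:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"projection sidecar {sidecar_path.name} is missing")
    sidecar = json.loads(sidecar_path.read_text())
    stack = np.asarray(nib.load(path).dataobj, dtype=np.float32)
    data = np.transpose(stack, (2, 0, 1))
    angles = np.asarray(sidecar["angles_deg"], dtype=np.float64)
    if data.shape[0] != angles.shape[0]:
        raise ValueError(
            f"sidecar lists {angles.shape[0]} views but the stack holds "
            f"{data.shape[0]}")
    width = sidecar.get("window_width_pct")
    return ProjectionSet(
        data, angles, float(sidecar["orbit_radius_mm"]),
        float(sidecar["pixel_mm"]),
        window_center_kev=sidecar.get("window_center_keV"),
        window_width_frac=None if width is None else width / 100.0,
        meta=sidecar.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One end-to-end run: phantom -> simulate -> dual reconstruction -> contrast."""

    out_dir: str = "dualspect_run"
    phantom_id: int = 3
    sector: str = "anterior"
    seed: int = 0
    count_scale: float = 1.0
    iterations: int = 10
    subsets: int = 8
    scatter_update_iters: int = 2
    photons: int = 100_000
    ds_photons: int = 1_000_000
    sim_photons: int = 1_000_000
    coarse_factor: int = 2
    postfilter_cm: float = 0.9
    study: dict = field(default_factory=dict)   # StudySpec overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the full workflow and write artifacts plus a manifest.

    Returns the manifest dictionary (stage wall-times, seeds, parameter
    hash, contrast results).  With ``dry_run`` only the stage plan is
    returned and nothing is computed or written.
    """
    plan = ["build_phantom", "simulate_study", "reconstruct_dual",
            "reconstruct_pure_tl", "analyze_contrast"]
    if dry_run:
        return {"plan": plan, "config": config.to_dict()}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
    manifest: dict = {"config": config.to_dict(), "config_hash": cfg_hash,
                      "seed": config.seed, "stages": {}}
    times: dict = {}

    def stage(name):
        times[name] = time.perf_counter()

    stage("build_phantom")
    spec = cardiac_phantom_spec(config.phantom_id)
    phantom = build_cardiac_phantom(spec)
    write_volume(out / "tc_activity.nii.gz", phantom.tc)
    write_volume(out / "tl_activity.nii.gz", phantom.tl)
    write_volume(out / "mu_map.nii.gz", phantom.mu_map)

    stage("simulate_study")
    study = StudySpec(count_scale=config.count_scale, **config.study)
    collimator = CollimatorModel()
    sim_mc = McConfig(photons=config.sim_photons,
                      coarse_factor=config.coarse_factor, seed=config.seed)
    sim = simulate_study(phantom, study, collimator, sim_mc, seed=config.seed)
    write_projections(out / "proj_tc.nii.gz", sim.tc)
    write_projections(out / "proj_tl_dual.nii.gz", sim.tl_dual)
    write_projections(out / "proj_tl_pure.nii.gz", sim.tl_pure)

    stage("reconstruct_dual")
    geometry = study.geometry()
    mc = McConfig(photons=config.photons, coarse_factor=config.coarse_factor,
                  seed=config.seed)
    recon_cfg = ReconConfig(iterations=config.iterations,
                            subsets=config.subsets,
                            scatter_update_iters=config.scatter_update_iters,
                            mc=mc, postfilter_fwhm_cm=config.postfilter_cm)
    ds_mc = McConfig(photons=config.ds_photons,
                     coarse_factor=config.coarse_factor, seed=config.seed)
    dual = reconstruct_dual(sim.tc, sim.tl_dual, phantom.mu_map, geometry,
                            collimator, recon_cfg, ds_mc, recon_cfg,
                            study.tc_window, study.tl_window,
                            study.resolution_frac)
    write_volume(out / "recon_tc.nii.gz", dual.tc)
    write_volume(out / "recon_tl.nii.gz", dual.tl)

    stage("reconstruct_pure_tl")
    from .reconstruct import SelfScatterProvider
    from .physics import TL201
    provider = SelfScatterProvider(phantom.mu_map, TL201, study.tl_window,
                                   geometry, collimator, mc,
                                   resolution_frac=study.resolution_frac)
    pure_vol, _ = osem(sim.tl_pure, phantom.mu_map, geometry, collimator,
                       recon_cfg, provider, emission=TL201,
                       window=study.tl_window,
                       resolution_frac=study.resolution_frac)
    write_volume(out / "recon_tl_pure.nii.gz", pure_vol)

    stage("analyze_contrast")
    results = {}
    for name, vol in (("tc", dual.tc), ("tl_dual", dual.tl),
                      ("tl_pure", pure_vol)):
        c = evaluate_contrast(vol, phantom, config.sector)
        results[name] = {
            "contrast_myocardium_defect": c.contrast_myocardium_defect,
            "contrast_myocardium_lv": c.contrast_myocardium_lv,
            "slice_index": c.slice_index, "roi_area": c.roi_area,
        }
    (out / "contrast.json").write_text(json.dumps(results, indent=1))

    end = time.perf_counter()
    names = plan
    for i, name in enumerate(names):
        t0 = times[name]
        t1 = times[names[i + 1]] if i + 1 < len(names) else end
        manifest["stages"][name] = {"wall_s": round(t1 - t0, 3)}
    manifest["contrast"] = results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
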