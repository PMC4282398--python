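"""Pipeline orchestration: simulate -> fitmaps -> track -> parcellate ->
covary -> roistats as one reproducible, manifest-logged run.

A single root seed fans out to per-stage derived seeds so stages are
independently reproducible. The run mirrors the two-cohort structure of the
original study design: a small tractography cohort defines the parcels, a
larger cohort supplies the parameter maps for covariance and subregion
statistics.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import PARAMETERS
from .covariance import (build_design, extract_seed_values, fit_voxelwise,
                         fwe_correct, report_peaks)
from .parcellation import DEFAULT_CLASS_DEF, aggregate_classes, zscore_maps, \
    group_average_parcel
from .phantom.atlas import build_atlas
from .phantom.cohort import CohortSpec, sample_cohort
from .phantom.fibers import build_fiber_field, default_fiber_spec
from .phantom.signals import synthesize_weighted_volumes, uniform_b1
from .protocol import mpm_protocol
from .qmaps import fit_maps
from .roistats import summarize_table1
from .study import _child_seed, _partner_voxels
from .tracking import StreamlineParams, track_classify


@dataclass
class RunConfig:
    """Configuration of one end-to-end phantom run."""

    out_dir: str = "bgvbq_run"
    rng_seed: int = 0
    stages: tuple[str, ...] = ("simulate", "track", "parcellate", "fitmaps",
                               "covary", "roistats")
    n_track_subjects: int = 13
    n_map_subjects: int = 101
    samples_per_voxel: int = 200
    dispersion_deg: float = 0.0
    noise_sd: float = 0.5
    parcel_mode: str = "tripartite"
    fwe_method: str = "permutation"
    n_perm: int = 200
    alpha: float = 0.05
    covary_seed: tuple[str, str] = ("limbic", "R2s")
    b1_correction: bool = False
    b1_path: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out = cls(**cfg)
        if isinstance(out.covary_seed, list):
            out.covary_seed = tuple(out.covary_seed)
        if isinstance(out.stages, list):
            out.stages = tuple(out.stages)
        return out

    def validate(self) -> None:
        if self.b1_correction and not self.b1_path:
            raise ValueError("b1_correction enabled but no b1_path configured")
        bad = set(self.stages) - {"simulate", "track", "parcellate",
                                  "fitmaps", "covary", "roistats"}
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    config.validate()
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}
    artifacts: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "track": _stage_track,
        "parcellate": _stage_parcellate,
        "fitmaps": _stage_fitmaps,
        "covary": _stage_covary,
        "roistats": _stage_roistats,
    }
    order = [s for s in ("simulate", "track", "parcellate", "fitmaps",
                         "covary", "roistats") if s in config.stages]
    for stage in order:
        t0 = time.time()
        stage_dir = out_root / stage
        try:
            files = stage_fns[stage](config, stage_dir, artifacts)
        except Exception as exc:  # noqa: BLE001 - quarantine then re-raise
            if stage_dir.exists():
                stage_dir.rename(stage_dir.with_name(stage + ".quarantine"))
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for name, path in files.items():
            manifest["files"][f"{stage}/{name}"] = {
                "path": str(path), "sha256": _sha256(Path(path))}
    manifest_path = out_root / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(config: RunConfig, out: Path, art: dict) -> dict:
    atlas = build_atlas()
    spec = CohortSpec(n_subjects=config.n_map_subjects,
                      rng_seed=_child_seed(config.rng_seed, 2))
    cohort = sample_cohort(atlas, spec)
    field = build_fiber_field(atlas, default_fiber_spec(
        atlas, dispersion_deg=config.dispersion_deg))
    art.update(atlas=atlas, cohort=cohort, field=field, spec=spec)
    files = {}
    files["labels"] = io.save_volume(out / "labels.nii.gz", atlas.labels,
                                     atlas.affine, np.int16)
    files["regions"] = io.save_tsv(atlas.regions, out / "regions.tsv")
    files["covariates"] = io.save_tsv(cohort.covariates, out / "covariates.tsv")
    files.update({f"field_{k}": v for k, v in
                  io.save_fiber_field(field, out / "field").items()})
    return files


def _stage_track(config: RunConfig, out: Path, art: dict) -> dict:
    atlas, field = art["atlas"], art["field"]
    targets = atlas.masks_by_role("cortical-target")
    conns = []
    for s in range(config.n_track_subjects):
        params = StreamlineParams(
            samples_per_voxel=config.samples_per_voxel,
            rng_seed=_child_seed(config.rng_seed, 11, s))
        conns.append(track_classify(field, atlas.seed_mask, targets, params))
    art["conns"] = conns
    files = {}
    waytotals = []
    for t in conns[0].counts:
        files[f"counts_{t}"] = io.save_volume(
            out / f"seeds_to_{t}.nii.gz", conns[0].count_map(t),
            atlas.affine, np.int32)
    for i, c in enumerate(conns):
        waytotals.append({"subject": i, "waytotal": c.waytotal})
    files["waytotal"] = io.save_tsv(pd.DataFrame(waytotals),
                                    out / "waytotal.tsv")
    return files


def _stage_parcellate(config: RunConfig, out: Path, art: dict) -> dict:
    atlas = art["atlas"]
    zmaps = [zscore_maps(aggregate_classes(c, DEFAULT_CLASS_DEF))
             for c in art["conns"]]
    parcel = group_average_parcel(zmaps, mode=config.parcel_mode)
    art["parcel"] = parcel
    files = {"parcels": io.save_volume(out / "parcels.nii.gz",
                                       parcel.label_volume(), atlas.affine,
                                       np.int16)}
    for cls in parcel.class_names:
        vol = np.zeros(parcel.shape, dtype=np.float32)
        vol[tuple(parcel.seed_voxels.T)] = parcel.exclusive[cls]
        files[f"exclusive_{cls}"] = io.save_volume(
            out / f"exclusive_{cls}.nii.gz", vol, atlas.affine)
    sizes = pd.DataFrame([{"class": k, "n_voxels": v}
                          for k, v in parcel.sizes().items()])
    files["sizes"] = io.save_tsv(sizes, out / "parcel_sizes.tsv")
    return files


def _stage_fitmaps(config: RunConfig, out: Path, art: dict) -> dict:
    atlas, cohort, spec = art["atlas"], art["cohort"], art["spec"]
    parcel = art["parcel"]
    protocol = mpm_protocol()
    b1 = None
    if config.b1_path:
        f, _ = io.load_volume(config.b1_path)
        from .core import B1Map
        b1 = B1Map(f=f)

    partner_vox, _ = _partner_voxels(atlas)
    partner_values = {p: np.empty((config.n_map_subjects, len(partner_vox)))
                      for p in PARAMETERS}

    def fitted():
        for j in range(config.n_map_subjects):
            truth = cohort.render_maps(j)
            rng = np.random.default_rng([spec.rng_seed, 97, j])
            echoes = synthesize_weighted_volumes(
                truth, protocol, b1=b1, noise_sd=config.noise_sd,
                mode="rational", rng=rng)
            maps = fit_maps(echoes, protocol, b1=b1, mask=truth.mask,
                            affine=atlas.affine)
            for p in PARAMETERS:
                partner_values[p][j] = maps.get(p)[tuple(partner_vox.T)]
            if j == 0:
                io.save_map_set(maps, out / "sub-000")
            yield maps

    table, counts = extract_seed_values(fitted(), parcel, cohort.covariates)
    art["cohort_table"] = table
    art["partner_values"] = partner_values
    art["partner_voxels"] = partner_vox
    files = {"cohort": io.save_tsv(table, out / "cohort.tsv")}
    files["parcel_voxels"] = io.save_tsv(
        pd.DataFrame([{"parcel": k, "n_voxels": v} for k, v in counts.items()]),
        out / "parcel_voxel_counts.tsv")
    for name in ("MT", "R1", "R2s", "A", "mask"):
        files[f"sub-000_{name}"] = out / "sub-000" / f"{name}.nii.gz"
    return files


def _stage_covary(config: RunConfig, out: Path, art: dict) -> dict:
    atlas = art["atlas"]
    table = art["cohort_table"]
    voxels = art["partner_voxels"]
    cls, parameter = config.covary_seed
    Y = art["partner_values"][parameter]
    X, contrast, names = build_design(table, (cls, parameter))
    result = fit_voxelwise({parameter: Y}, {parameter: X}, contrast,
                           voxels=voxels, column_names=names)[parameter]
    result = fwe_correct(result, method=config.fwe_method,
                         n_perm=config.n_perm, alpha=config.alpha,
                         rng_seed=_child_seed(config.rng_seed, 56))
    peaks = report_peaks(result, atlas.shape, atlas.affine)
    t_vol = np.zeros(atlas.shape, dtype=np.float32)
    t_vol[tuple(voxels.T)] = result.t
    cp_vol = np.ones(atlas.shape, dtype=np.float32)
    cp_vol[tuple(voxels.T)] = result.corrected_p
    files = {
        "tmap": io.save_volume(out / f"t_{cls}_{parameter}.nii.gz", t_vol,
                               atlas.affine),
        "corrected_p": io.save_volume(out / f"pfwe_{cls}_{parameter}.nii.gz",
                                      cp_vol, atlas.affine),
        "peaks": io.save_tsv(peaks, out / "peaks.tsv"),
    }
    return files


def _stage_roistats(config: RunConfig, out: Path, art: dict) -> dict:
    summary = summarize_table1(art["cohort_table"])
    return {
        "subregion_table": io.save_tsv(summary.to_table(),
                                       out / "subregion_table.tsv"),
        "anova": io.save_tsv(summary.anova, out / "anova.tsv"),
        "paired": io.save_tsv(summary.paired, out / "paired_tests.tsv"),
    }


def validate_nifti_bundle(paths) -> list[dict]:
    """Consistency report over a set of NIfTI volumes.

    Checks grid/affine agreement, reports dtype and excessive-NaN warnings.
    Returns a list of issue dicts (empty = consistent bundle).
    """
    import nibabel as nib

    issues = []
    ref_shape = ref_affine = None
    for p in paths:
        img = nib.load(str(p))
        data = np.asarray(img.dataobj)
        shape3 = img.shape[:3]
        if ref_shape is None:
            ref_shape, ref_affine = shape3, img.affine
        else:
            if shape3 != ref_shape:
                issues.append({"file": str(p), "level": "error",
                               "issue": f"grid {shape3} != {ref_shape}"})
            if not np.allclose(img.affine, ref_affine, atol=1e-4):
                issues.append({"file": str(p), "level": "error",
                               "issue": "affine mismatch"})
        if np.issubdtype(data.dtype, np.floating):
            nan_frac = float(np.isnan(data).mean())
            if nan_frac > 0.5:
                issues.append({"file": str(p), "level": "warning",
                               "issue": f"NaN fraction {nan_frac:.2f} > 0.5"})
    return issues
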