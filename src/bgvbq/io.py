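"""NIfTI / TSV / YAML reading and writing via nibabel, pandas and pyyaml."""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import B1Map, ParameterMapSet
from .tracking import FiberField


def save_volume(path, data: np.ndarray, affine: np.ndarray,
                dtype=np.float32) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), affine)
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_map_set(maps: ParameterMapSet, out_dir, prefix: str = "") -> dict[str, Path]:
    out = {}
    for name, vol, dtype in (("MT", maps.mt, np.float32),
                             ("R1", maps.r1, np.float32),
                             ("R2s", maps.r2s, np.float32),
                             ("A", maps.a_app, np.float32),
                             ("mask", maps.mask, np.int16)):
        out[name] = save_volume(Path(out_dir) / f"{prefix}{name}.nii.gz",
                                vol, maps.affine, dtype)
    return out


def save_fiber_field(field: FiberField, out_dir) -> dict[str, Path]:
    """Paired 4D vector volumes + fraction volumes (+ mask)."""
    out_dir = Path(out_dir)
    out = {}
    for k in range(2):
        out[f"dyads{k + 1}"] = save_volume(out_dir / f"dyads{k + 1}.nii.gz",
                                           field.orientations[..., k, :],
                                           field.affine)
        out[f"f{k + 1}"] = save_volume(out_dir / f"mean_f{k + 1}.nii.gz",
                                       field.fractions[..., k], field.affine)
    out["mask"] = save_volume(out_dir / "nodif_brain_mask.nii.gz",
                              field.mask, field.affine, np.int16)
    return out


def load_fiber_field(in_dir, dispersion_deg: float = 0.0) -> FiberField:
    in_dir = Path(in_dir)
    d1, affine = load_volume(in_dir / "dyads1.nii.gz")
    d2, _ = load_volume(in_dir / "dyads2.nii.gz")
    f1, _ = load_volume(in_dir / "mean_f1.nii.gz")
    f2, _ = load_volume(in_dir / "mean_f2.nii.gz")
    mask, _ = load_volume(in_dir / "nodif_brain_mask.nii.gz")
    return FiberField(
        orientations=np.stack([d1, d2], axis=-2).astype(np.float64),
        fractions=np.stack([f1, f2], axis=-1).astype(np.float64),
        mask=mask > 0.5, affine=affine, dispersion_deg=dispersion_deg)


def save_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
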