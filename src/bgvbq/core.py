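"""Shared containers for volumetric data.

All volumes in a bundle live on a common voxel grid with a common RAS
voxel-to-world affine. Voxel indices are 0-based; world coordinates are mm.
Masks use value > 0.5 semantics throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

PARAMETERS = ("MT", "R1", "R2s")
#: display names with units used in reports
PARAMETER_UNITS = {"MT": "%", "R1": "s^-1", "R2s": "s^-1"}


def default_affine(shape: tuple[int, int, int], voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """RAS affine with 1 mm (by default) isotropic voxels, origin at grid center."""
    aff = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * np.asarray(voxel_size)
    return aff


def world_from_voxel(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.atleast_2d(ijk)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def voxel_from_world(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    xyz = np.atleast_2d(xyz)
    inv = np.linalg.inv(affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class ParameterMapSet:
    """Co-registered quantitative maps for one subject.

    MT saturation is stored in percent units; R1 and R2* in s^-1; A_app in
    arbitrary signal units. ``mask`` is the shared analysis mask: voxels
    flagged invalid by any estimator are removed from it.
    """

    mt: np.ndarray
    r1: np.ndarray
    r2s: np.ndarray
    a_app: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        shapes = {self.mt.shape, self.r1.shape, self.r2s.shape, self.a_app.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"parameter maps must share one grid, got shapes {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mt.shape

    def get(self, parameter: str) -> np.ndarray:
        try:
            return {"MT": self.mt, "R1": self.r1, "R2s": self.r2s, "A": self.a_app}[parameter]
        except KeyError:
            raise KeyError(f"unknown parameter {parameter!r}; expected one of MT, R1, R2s, A")

    def copy(self) -> "ParameterMapSet":
        return replace(
            self,
            mt=self.mt.copy(),
            r1=self.r1.copy(),
            r2s=self.r2s.copy(),
            a_app=self.a_app.copy(),
            mask=self.mask.copy(),
        )


@dataclass
class B1Map:
    """Relative transmit-field map: realized flip angle = f * nominal (f=1 nominal)."""

    f: np.ndarray

    def validate(self, mask: np.ndarray | None = None) -> None:
        f = self.f if mask is None else self.f[mask > 0.5]
        if np.any(f <= 0):
            raise ValueError("B1 factor must be strictly positive inside the mask")
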