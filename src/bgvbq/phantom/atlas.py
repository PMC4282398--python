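"""Synthetic label atlas for a desk-scale basal-ganglia phantom.

The default layout places, on a 48x56x48 grid at 1 mm isotropic resolution
(axes: x = left-right, y = posterior-anterior, z = inferior-superior):

* a bilateral tripartite seed nucleus (the subthalamic nucleus stand-in) of
  36 voxels per hemisphere, split into three 12-voxel slabs — motor
  (posterolateral), associative (central), limbic (anteromedial);
* subcortical circuit-partner blocks: posterior putamen and thalamus (motor
  circuit), dorsal pallidum and caudate (associative), anterior putamen and
  ventral pallidum (limbic);
* eight target regions: six cortical slabs (M1, SMA, superior frontal,
  middle frontal, anterior cingulate, orbitofrontal) plus hippocampus and
  amygdala blocks, each assigned to one circuit;
* a "brain" filler region covering the rest of the brain mask.

Geometric realism is deliberately coarse: regions are axis-aligned blocks
whose adjacency relations (not shapes) mimic the basal ganglia.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..core import default_affine

SEED_ROLES = ("seed-motor", "seed-associative", "seed-limbic")
ROLES = SEED_ROLES + ("circuit-partner", "cortical-target", "other")
CIRCUITS = ("motor", "associative", "limbic", "none")

#: template grid the default layout is designed on
TEMPLATE_SHAPE = (48, 56, 48)


class AtlasSizingError(ValueError):
    """Grid too small to host all regions of the requested layout."""


@dataclass
class PhantomAtlas:
    """Integer label volume plus a region table.

    ``regions`` columns: label, name, role, circuit, hemisphere.
    ``labels`` == 0 is background (outside the brain mask).
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def label_of(self, name: str) -> int:
        rows = self.regions.loc[self.regions["name"] == name, "label"]
        if rows.empty:
            raise KeyError(f"no region named {name!r}")
        return int(rows.iloc[0])

    def mask_of(self, name: str) -> np.ndarray:
        return self.labels == self.label_of(name)

    def masks_by_role(self, role: str) -> dict[str, np.ndarray]:
        sub = self.regions[self.regions["role"] == role]
        return {r["name"]: self.labels == r["label"] for _, r in sub.iterrows()}

    @property
    def seed_mask(self) -> np.ndarray:
        seed_labels = self.regions.loc[self.regions["role"].isin(SEED_ROLES), "label"]
        return np.isin(self.labels, seed_labels.to_numpy())

    def seed_ground_truth(self) -> np.ndarray:
        """Label volume with 1 motor / 2 associative / 3 limbic over seed voxels."""
        out = np.zeros(self.shape, dtype=np.int16)
        for value, role in enumerate(SEED_ROLES, start=1):
            for _, row in self.regions[self.regions["role"] == role].iterrows():
                out[self.labels == row["label"]] = value
        return out

    def validate(self) -> None:
        labels = self.labels
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(labels)) - {0}
        tabled = set(self.regions["label"].tolist())
        if present - tabled:
            raise ValueError(f"labels missing from region table: {sorted(present - tabled)}")
        if self.regions["label"].duplicated().any():
            raise ValueError("duplicate labels in region table")
        for hemi in ("L", "R"):
            sel = self.regions["role"].isin(SEED_ROLES) & (self.regions["hemisphere"] == hemi)
            n = int(np.isin(labels, self.regions.loc[sel, "label"].to_numpy()).sum())
            if n < 30:
                raise ValueError(f"seed hemisphere {hemi} has {n} voxels (< 30)")
        seed = self.seed_mask
        targets = self.regions.loc[self.regions["role"] == "cortical-target", "label"]
        if np.any(seed & np.isin(labels, targets.to_numpy())):
            raise ValueError("seed and target regions overlap")


def _mirror(sl: tuple[slice, slice, slice], nx: int) -> tuple[slice, slice, slice]:
    """Mirror an x-slice across the grid midline (left <-> right)."""
    x = sl[0]
    return (slice(nx - x.stop, nx - x.start), sl[1], sl[2])


def _template_regions() -> list[tuple[str, str, str, str, tuple[slice, slice, slice]]]:
    """(name, role, circuit, hemisphere, block) in template voxel coordinates."""

    def box(x0, x1, y0, y1, z0, z1):
        # inclusive voxel ranges
        return (slice(x0, x1 + 1), slice(y0, y1 + 1), slice(z0, z1 + 1))

    nx = TEMPLATE_SHAPE[0]
    left: list[tuple[str, str, str, tuple]] = [
        # tripartite seed nucleus: 4 x 1 x 3 voxel slabs stacked along y,
        # motor shifted laterally, limbic medially (posterolateral->anteromedial)
        ("stn_motor", "seed-motor", "motor", box(13, 16, 25, 25, 19, 21)),
        ("stn_associative", "seed-associative", "associative", box(14, 17, 26, 26, 19, 21)),
        ("stn_limbic", "seed-limbic", "limbic", box(15, 18, 27, 27, 19, 21)),
        # circuit partners (5x5x5 blocks)
        ("putamen_posterior", "circuit-partner", "motor", box(3, 7, 14, 18, 14, 18)),
        ("thalamus", "circuit-partner", "motor", box(19, 23, 16, 20, 18, 22)),
        ("pallidum_dorsal", "circuit-partner", "associative", box(7, 11, 24, 28, 25, 29)),
        ("caudate", "circuit-partner", "associative", box(8, 12, 33, 37, 26, 30)),
        ("putamen_anterior", "circuit-partner", "limbic", box(3, 7, 30, 34, 14, 18)),
        ("pallidum_ventral", "circuit-partner", "limbic", box(7, 11, 29, 33, 8, 12)),
        # subcortical limbic targets
        ("hippocampus", "cortical-target", "limbic", box(3, 7, 38, 42, 3, 7)),
        ("amygdala", "cortical-target", "limbic", box(3, 7, 44, 48, 3, 7)),
    ]
    # cortical slabs span both hemispheres
    slabs = [
        ("m1", "motor", box(6, 41, 10, 15, 40, 43)),
        ("sma", "motor", box(6, 41, 17, 21, 40, 43)),
        ("superior_frontal", "associative", box(6, 41, 24, 29, 40, 43)),
        ("middle_frontal", "associative", box(6, 41, 31, 35, 40, 43)),
        ("acc", "limbic", box(6, 41, 38, 43, 40, 43)),
        ("ofc", "limbic", box(6, 41, 45, 49, 40, 43)),
    ]
    out = []
    for name, role, circuit, block in left:
        out.append((f"{name}_l", role, circuit, "L", block))
        out.append((f"{name}_r", role, circuit, "R", _mirror(block, nx)))
    for name, circuit, block in slabs:
        out.append((name, "cortical-target", circuit, "B", block))
    return out


#: brain-mask box of the template layout (inclusive voxel ranges)
TEMPLATE_BRAIN_BOX = ((2, 45), (2, 53), (2, 45))


def build_atlas(grid_shape=TEMPLATE_SHAPE, layout: str = "default",
                voxel_size=(1.0, 1.0, 1.0)) -> PhantomAtlas:
    """Build the default phantom atlas, centered on ``grid_shape``.

    Deterministic for fixed inputs. Grids smaller than the 48x56x48 template
    (or below the 24^3 hard floor) raise :class:`AtlasSizingError`.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if layout != "default":
        raise ValueError(f"unknown layout {layout!r}")
    if any(s < 24 for s in grid_shape):
        raise AtlasSizingError(f"grid {grid_shape} below the 24^3 minimum")
    if any(g < t for g, t in zip(grid_shape, TEMPLATE_SHAPE)):
        raise AtlasSizingError(
            f"grid {grid_shape} too small to host the default layout "
            f"(needs at least {TEMPLATE_SHAPE})")
    offset = tuple((g - t) // 2 for g, t in zip(grid_shape, TEMPLATE_SHAPE))

    labels = np.zeros(grid_shape, dtype=np.int16)
    rows = []
    # brain filler first so specific regions overwrite it
    (bx0, bx1), (by0, by1), (bz0, bz1) = TEMPLATE_BRAIN_BOX
    brain_sl = tuple(slice(a + o, b + 1 + o) for (a, b), o in
                     zip(TEMPLATE_BRAIN_BOX, offset))
    next_label = 1
    labels[brain_sl] = next_label
    rows.append({"label": next_label, "name": "brain", "role": "other",
                 "circuit": "none", "hemisphere": "B"})
    for name, role, circuit, hemi, block in _template_regions():
        next_label += 1
        sl = tuple(slice(s.start + o, s.stop + o) for s, o in zip(block, offset))
        labels[sl] = next_label
        rows.append({"label": next_label, "name": name, "role": role,
                     "circuit": circuit, "hemisphere": hemi})
    atlas = PhantomAtlas(
        labels=labels,
        regions=pd.DataFrame(rows),
        voxel_size=tuple(float(v) for v in voxel_size),
        affine=default_affine(grid_shape, voxel_size),
    )
    atlas.validate()
    return atlas
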