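"""Synthetic fiber-orientation fields from tube-shaped tract specifications.

Each tract is a polyline centerline (mm world coordinates) with a tube
radius and a volume fraction. Voxels whose center lies within the radius of
a centerline segment (finite cylinders, no end caps) receive the local
tangent as an orientation with the tube's fraction; a second overlapping
tube fills the second orientation slot, a third overlap is an error.

Inside the seed nucleus only voxels belonging to the tract's source
subregion are painted: a seed voxel's orientations represent that voxel's
own efferents, so a tube passing within its radius of a neighboring
subregion must not recruit it. This keeps thin adjacent subregions from
cross-contaminating each other's connectivity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import voxel_from_world, world_from_voxel
from ..tracking import FiberField
from .atlas import SEED_ROLES, PhantomAtlas


@dataclass
class TractSpec:
    source: str  # region name (seed subregion)
    target: str  # region name
    waypoints_mm: np.ndarray  # (K, 3), starts in source, ends in target
    radius_mm: float | tuple[float, ...] = 2.0  # scalar or per segment
    fraction: float = 1.0

    def __post_init__(self):
        self.waypoints_mm = np.asarray(self.waypoints_mm, dtype=float)
        if self.waypoints_mm.ndim != 2 or self.waypoints_mm.shape[0] < 2:
            raise ValueError("centerline needs at least two waypoints")
        n_seg = self.waypoints_mm.shape[0] - 1
        if np.isscalar(self.radius_mm):
            self.radius_mm = (float(self.radius_mm),) * n_seg
        else:
            self.radius_mm = tuple(float(r) for r in self.radius_mm)
        if len(self.radius_mm) != n_seg:
            raise ValueError("need one radius per centerline segment")
        if any(r <= 0 for r in self.radius_mm):
            raise ValueError("tube radius must be > 0")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("tube fraction must be in (0, 1]")


@dataclass
class FiberFieldSpec:
    tracts: list[TractSpec]
    dispersion_deg: float = 0.0


class TractOverlapError(ValueError):
    """More than two tubes claim one voxel."""


def _segment_voxels(p0, p1, radius, shape, affine):
    """Voxel indices within ``radius`` of segment [p0, p1] (capsule)."""
    v0 = voxel_from_world(affine, p0)[0]
    v1 = voxel_from_world(affine, p1)[0]
    vs = np.abs(np.diag(affine)[:3])
    r_vox = radius / vs  # per-axis radius in voxel units
    lo = np.maximum(np.floor(np.minimum(v0, v1) - r_vox.max()).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(v0, v1) + r_vox.max()).astype(int) + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    grid = np.stack(np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    pts = world_from_voxel(affine, grid.astype(float))
    axis = p1 - p0
    length = np.linalg.norm(axis)
    u = axis / length
    rel = pts - p0
    t = np.clip(rel @ u, 0.0, length)  # capsule: rounded end caps
    dist = np.linalg.norm(rel - np.outer(t, u), axis=1)
    return grid[dist <= radius]


def build_fiber_field(atlas: PhantomAtlas, spec: FiberFieldSpec) -> FiberField:
    """Paint tube tracts into a two-compartment fiber-orientation field."""
    shape = atlas.shape
    orientations = np.zeros(shape + (2, 3), dtype=np.float64)
    fractions = np.zeros(shape + (2,), dtype=np.float64)
    n_orient = np.zeros(shape, dtype=np.int8)

    seed_labels = atlas.regions.loc[atlas.regions["role"].isin(SEED_ROLES),
                                    ["label", "name"]]
    seed_label_set = set(seed_labels["label"].tolist())
    label_of = dict(zip(seed_labels["name"], seed_labels["label"]))

    for tract in spec.tracts:
        wp = tract.waypoints_mm
        src_mask = atlas.mask_of(tract.source)
        tgt_mask = atlas.mask_of(tract.target)
        v_start = np.floor(voxel_from_world(atlas.affine, wp[0])[0] + 0.5).astype(int)
        v_end = np.floor(voxel_from_world(atlas.affine, wp[-1])[0] + 0.5).astype(int)
        if not src_mask[tuple(v_start)]:
            raise ValueError(f"tract {tract.source}->{tract.target}: centerline "
                             f"start not inside source region {tract.source!r}")
        if not tgt_mask[tuple(v_end)]:
            raise ValueError(f"tract {tract.source}->{tract.target}: centerline "
                             f"end not inside target region {tract.target!r}")
        src_label = label_of.get(tract.source)
        # collect (voxel, tangent), last segment wins where segments overlap
        claimed: dict[tuple, np.ndarray] = {}
        for k in range(wp.shape[0] - 1):
            seg = wp[k + 1] - wp[k]
            tangent = seg / np.linalg.norm(seg)
            for ijk in _segment_voxels(wp[k], wp[k + 1], tract.radius_mm[k],
                                       shape, atlas.affine):
                claimed[tuple(ijk)] = tangent
        for ijk, tangent in claimed.items():
            lab = atlas.labels[ijk]
            if lab in seed_label_set and lab != src_label:
                continue  # seed voxels carry only their own subregion's efferents
            slot = n_orient[ijk]
            if slot >= 2:
                raise TractOverlapError(
                    f"voxel {ijk} claimed by more than two tracts")
            orientations[ijk][slot] = tangent
            fractions[ijk][slot] = tract.fraction
            n_orient[ijk] += 1

    total = fractions.sum(axis=-1)
    if np.any(total > 1.0 + 1e-9):
        raise ValueError("per-voxel tube fractions sum to > 1")
    fib = FiberField(orientations=orientations, fractions=fractions,
                     mask=atlas.brain_mask.copy(), affine=atlas.affine,
                     dispersion_deg=spec.dispersion_deg)
    # orientations may fall outside the brain mask if a tube exits it; clip
    outside = ~fib.mask
    fib.fractions[outside] = 0.0
    fib.orientations[outside] = 0.0
    fib.validate()
    return fib


def default_fiber_spec(atlas: PhantomAtlas, dispersion_deg: float = 0.0,
                       radius_mm: float = 2.0,
                       bend_radius_mm: float = 2.8) -> FiberFieldSpec:
    """One tube per seed subregion and hemisphere to its primary class target.

    Routes (template geometry, mirrored for the right hemisphere): the motor
    subregion exits posteriorly then ascends to M1; the associative
    subregion ascends straight to superior frontal cortex; the limbic
    subregion exits anteriorly then ascends to the anterior cingulate slab.
    All bends are 45 degrees, well inside the default curvature threshold.
    The segments past the first bend use the wider ``bend_radius_mm`` so that
    off-axis streamlines survive the elbows; near the seed the narrow
    ``radius_mm`` keeps the three class pathways disjoint.
    """

    def center(name):
        vox = np.argwhere(atlas.labels == atlas.label_of(name))
        return world_from_voxel(atlas.affine, vox.mean(axis=0))[0]

    def w(x, y, z):
        return world_from_voxel(atlas.affine, np.array([x, y, z], float))[0]

    tracts = []
    for hemi in ("l", "r"):
        cm = center(f"stn_motor_{hemi}")
        ca = center(f"stn_associative_{hemi}")
        cl = center(f"stn_limbic_{hemi}")
        xm, xa, xl = cm[0], ca[0], cl[0]
        vm = voxel_from_world(atlas.affine, cm)[0]
        # waypoints built in voxel space around each subregion's own x column
        def vox_pts(x_world, pts):
            out = []
            for (y, z) in pts:
                p = voxel_from_world(atlas.affine, np.array([x_world, 0, 0.]))[0]
                out.append(w(p[0], y, z))
            return np.asarray(out)

        y0, z0 = vm[1], vm[2]
        tracts.append(TractSpec(
            source=f"stn_motor_{hemi}", target="m1",
            waypoints_mm=vox_pts(xm, [(y0, z0), (y0 - 9, z0),
                                      (y0 - 12, z0 + 3), (y0 - 12, z0 + 22)]),
            radius_mm=(radius_mm, bend_radius_mm, bend_radius_mm)))
        tracts.append(TractSpec(
            source=f"stn_associative_{hemi}", target="superior_frontal",
            waypoints_mm=vox_pts(xa, [(y0 + 1, z0 - 1), (y0 + 1, z0 + 22)]),
            radius_mm=radius_mm))
        tracts.append(TractSpec(
            source=f"stn_limbic_{hemi}", target="acc",
            waypoints_mm=vox_pts(xl, [(y0 + 2, z0), (y0 + 11, z0),
                                      (y0 + 15, z0 + 4), (y0 + 15, z0 + 22)]),
            radius_mm=(radius_mm, bend_radius_mm, bend_radius_mm)))
    return FiberFieldSpec(tracts=tracts, dispersion_deg=dispersion_deg)
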