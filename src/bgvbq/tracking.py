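"""Probabilistic streamline tractography with classification-target counting.

The fiber model stores up to two unit orientations with volume fractions per
voxel (a two-compartment stick model). Propagation follows the reference
probabilistic-tractography convention: nearest-voxel orientation lookup
(positions stay continuous), per-step sampling of a compartment proportional
to its fraction, an angular Gaussian perturbation standing in for the
orientation posterior, sign alignment with the previous direction, and
termination on mask exit, missing orientations, or a curvature threshold
expressed as a minimum cosine between successive step directions.

``track_classify`` launches a fixed number of tracts per seed voxel from
uniformly jittered start points; each tract is the union of two propagations
(initial direction and its antipode) and increments a target's count at most
once, giving per-target count maps over seed voxels with a fixed waytotal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TERMINATION = ("active", "mask", "no_orientation", "curvature", "max_steps")


@dataclass
class FiberField:
    """Up to two unit orientations + fractions per voxel, with a brain mask.

    ``orientations``: (X, Y, Z, 2, 3); ``fractions``: (X, Y, Z, 2);
    ``dispersion_deg``: global angular SD of the orientation perturbation.
    Orientations are axial (sign-free): v and -v are equivalent.
    """

    orientations: np.ndarray
    fractions: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    dispersion_deg: float = 0.0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    def validate(self) -> None:
        if self.dispersion_deg < 0:
            raise ValueError("dispersion must be >= 0")
        frac = self.fractions
        if np.any(frac < 0) or np.any(frac.sum(axis=-1) > 1.0 + 1e-6):
            raise ValueError("fractions must be >= 0 and sum to <= 1 per voxel")
        norms = np.linalg.norm(self.orientations, axis=-1)
        bad = (frac > 0) & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            raise ValueError("orientations with nonzero fraction must be unit vectors")
        if np.any((frac.sum(axis=-1) > 0) & ~self.mask):
            raise ValueError("orientation voxels must lie inside the brain mask")


@dataclass
class StreamlineParams:
    samples_per_voxel: int = 5000
    step: float = 0.5  # mm
    curvature_threshold: float = 0.2  # min cosine between successive steps
    max_steps: int = 2000
    rng_seed: int = 0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if not (0.0 <= self.curvature_threshold < 1.0):
            raise ValueError("curvature threshold must be in [0, 1)")
        if self.samples_per_voxel < 1:
            raise ValueError("samples_per_voxel must be >= 1")


@dataclass
class ConnectivityMaps:
    """Per-target streamline counts over seed voxels (waytotal per voxel)."""

    seed_voxels: np.ndarray  # (N, 3) int
    counts: dict[str, np.ndarray]  # target -> (N,) int
    waytotal: int
    shape: tuple[int, ...]
    affine: np.ndarray

    def count_map(self, target: str) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=np.int32)
        vol[tuple(self.seed_voxels.T)] = self.counts[target]
        return vol

    def validate(self) -> None:
        for name, c in self.counts.items():
            if np.any(c < 0) or np.any(c > self.waytotal):
                raise ValueError(f"counts for target {name!r} outside [0, waytotal]")


def _canonical(d: np.ndarray) -> np.ndarray:
    """Resolve the sign ambiguity of axial orientations (lexicographic)."""
    sign = np.where(d[..., 0] != 0, np.sign(d[..., 0]),
                    np.where(d[..., 1] != 0, np.sign(d[..., 1]),
                             np.sign(d[..., 2])))
    sign = np.where(sign == 0, 1.0, sign)
    return d * sign[..., None]


def _perturb(d: np.ndarray, sigma_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate each unit vector by angle |N(0, sigma)| with uniform azimuth."""
    n = d.shape[0]
    theta = np.abs(rng.normal(0.0, sigma_rad, n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    helper = np.where(np.abs(d[:, 2:3]) < 0.9,
                      np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    st = np.sin(theta)
    return (np.cos(theta)[:, None] * d
            + (st * np.cos(phi))[:, None] * e1
            + (st * np.sin(phi))[:, None] * e2)


def _sample_direction(field: FiberField, ijk: np.ndarray,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample one (canonical, perturbed) orientation per row of ``ijk``.

    Returns (directions (n,3), has_orientation (n,) bool).
    """
    fr = field.fractions[ijk[:, 0], ijk[:, 1], ijk[:, 2]]  # (n, 2)
    fsum = fr.sum(axis=1)
    ok = fsum > 0
    u = rng.uniform(size=ijk.shape[0])
    k = (u * fsum >= fr[:, 0]).astype(int)  # second compartment when u*fsum >= f0
    d = field.orientations[ijk[:, 0], ijk[:, 1], ijk[:, 2], k]
    d = _canonical(d)
    if field.dispersion_deg > 0:
        d_pert = np.zeros_like(d)
        if ok.any():
            d_pert[ok] = _perturb(d[ok], np.deg2rad(field.dispersion_deg), rng)
        d = d_pert
    return d, ok


def _voxel_of(pos: np.ndarray) -> np.ndarray:
    # voxel i covers [i - 0.5, i + 0.5) in continuous voxel coordinates
    return np.floor(pos + 0.5).astype(np.int64)


def _propagate_batch(field: FiberField, pos: np.ndarray, prev: np.ndarray,
                     params: StreamlineParams, rng: np.random.Generator,
                     target_ids: np.ndarray | None = None,
                     n_targets: int = 0,
                     paths: list | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Propagate a batch of streamlines in continuous voxel coordinates.

    ``prev`` is the launch direction (used as the first step). Returns
    (hits (N, n_targets) bool, reason codes (N,) indexing TERMINATION).
    """
    shape = np.asarray(field.shape)
    step_vox = params.step  # voxel size folded into mm grids by the caller
    n = pos.shape[0]
    pos = pos.copy()
    prev = prev.copy()
    hits = np.zeros((n, n_targets), dtype=bool)
    reason = np.zeros(n, dtype=np.int8)  # 0 = active
    active = np.ones(n, dtype=bool)

    def mark_hits(idx, p):
        if target_ids is None:
            return
        ijk = _voxel_of(p)
        inb = np.all((ijk >= 0) & (ijk < shape), axis=1)
        tid = np.full(len(idx), 0, dtype=np.int32)
        tid[inb] = target_ids[ijk[inb, 0], ijk[inb, 1], ijk[inb, 2]]
        has = tid > 0
        hits[idx[has], tid[has] - 1] = True

    idx_all = np.arange(n)
    mark_hits(idx_all, pos)
    if paths is not None:
        paths.append(pos.copy())

    for step_i in range(params.max_steps):
        idx = idx_all[active]
        if idx.size == 0:
            break
        p = pos[idx]
        ijk = _voxel_of(p)
        inb = np.all((ijk >= 0) & (ijk < shape), axis=1)
        in_mask = inb.copy()
        in_mask[inb] = field.mask[ijk[inb, 0], ijk[inb, 1], ijk[inb, 2]]
        dead = ~in_mask
        if dead.any():
            reason[idx[dead]] = TERMINATION.index("mask")
            active[idx[dead]] = False
            idx, p, ijk = idx[in_mask], p[in_mask], ijk[in_mask]
            if idx.size == 0:
                continue
        if step_i == 0:
            d = prev[idx]
        else:
            d, ok = _sample_direction(field, ijk, rng)
            if (~ok).any():
                reason[idx[~ok]] = TERMINATION.index("no_orientation")
                active[idx[~ok]] = False
                idx, p, d = idx[ok], p[ok], d[ok]
                if idx.size == 0:
                    continue
            dots = np.einsum("ij,ij->i", prev[idx], d)
            flip = dots < 0
            d[flip] *= -1.0
            dots = np.abs(dots)
            bend = dots < params.curvature_threshold
            if bend.any():
                reason[idx[bend]] = TERMINATION.index("curvature")
                active[idx[bend]] = False
                idx, p, d = idx[~bend], p[~bend], d[~bend]
                if idx.size == 0:
                    continue
        new_pos = p + step_vox * d
        pos[idx] = new_pos
        prev[idx] = d
        mark_hits(idx, new_pos)
        if paths is not None:
            paths.append(pos.copy())
    still = active
    reason[still] = TERMINATION.index("max_steps")
    return hits, reason


def _voxel_step(field: FiberField, params: StreamlineParams) -> StreamlineParams:
    """Convert the mm step length into continuous voxel units (isotropic grids)."""
    vs = np.abs(np.diag(field.affine)[:3])
    if not np.allclose(vs, vs[0]):
        raise ValueError("anisotropic voxel grids are not supported")
    p = StreamlineParams(samples_per_voxel=params.samples_per_voxel,
                         step=params.step / vs[0],
                         curvature_threshold=params.curvature_threshold,
                         max_steps=params.max_steps, rng_seed=params.rng_seed)
    return p


def propagate_streamline(field: FiberField, start_mm: np.ndarray,
                         initial_direction: np.ndarray,
                         params: StreamlineParams,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[np.ndarray, str]:
    """Propagate a single streamline; returns (path points in mm, reason)."""
    from .core import voxel_from_world, world_from_voxel

    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    p = _voxel_step(field, params)
    pos0 = voxel_from_world(field.affine, np.asarray(start_mm, dtype=float))
    ijk0 = _voxel_of(pos0)[0]
    if (np.any(ijk0 < 0) or np.any(ijk0 >= np.asarray(field.shape))
            or not field.mask[tuple(ijk0)]):
        raise ValueError(f"start point {start_mm} outside the brain mask")
    d0 = np.asarray(initial_direction, dtype=float)[None, :]
    d0 = d0 / np.linalg.norm(d0)
    paths: list = []
    _, reason = _propagate_batch(field, pos0, d0, p, rng, paths=paths)
    path_vox = np.concatenate(paths, axis=0)
    return world_from_voxel(field.affine, path_vox), TERMINATION[int(reason[0])]


#: seed-voxel chunking constant (streamlines per chunk, keeps memory bounded)
_CHUNK_STREAMLINES = 250_000


def track_classify(field: FiberField, seed_mask: np.ndarray,
                   targets: dict[str, np.ndarray],
                   params: StreamlineParams) -> ConnectivityMaps:
    """Classification-targets tractography from every seed voxel.

    Per seed voxel, ``samples_per_voxel`` tracts are launched from uniformly
    jittered start points; each tract is the union of a propagation along a
    direction sampled from the voxel's orientation distribution and one along
    its antipode. Deterministic for fixed ``params.rng_seed``.
    """
    field.validate()
    if not np.any(seed_mask > 0.5):
        raise ValueError("empty seed mask")
    names = list(targets)
    target_ids = np.zeros(field.shape, dtype=np.int32)
    for t, name in enumerate(names, start=1):
        m = targets[name] > 0.5
        if np.any(target_ids[m] != 0):
            raise ValueError("targets must be pairwise disjoint")
        target_ids[m] = t
    p = _voxel_step(field, params)

    seed_voxels = np.argwhere(seed_mask > 0.5)
    n_seed, s = len(seed_voxels), p.samples_per_voxel
    counts = {name: np.zeros(n_seed, dtype=np.int32) for name in names}

    vox_per_chunk = max(1, _CHUNK_STREAMLINES // s)
    for ci, lo in enumerate(range(0, n_seed, vox_per_chunk)):
        hi = min(lo + vox_per_chunk, n_seed)
        rng = np.random.default_rng([params.rng_seed, 7919, ci])
        vox = np.repeat(seed_voxels[lo:hi], s, axis=0).astype(float)
        pos0 = vox + rng.uniform(-0.5, 0.5, vox.shape)
        ijk0 = _voxel_of(pos0)
        d0, ok = _sample_direction(field, ijk0, rng)
        hits_f, _ = _propagate_batch(field, pos0[ok], d0[ok], p, rng,
                                     target_ids=target_ids, n_targets=len(names))
        hits_b, _ = _propagate_batch(field, pos0[ok], -d0[ok], p, rng,
                                     target_ids=target_ids, n_targets=len(names))
        hits = np.zeros((len(vox), len(names)), dtype=bool)
        hits[ok] = hits_f | hits_b
        per_voxel = hits.reshape(hi - lo, s, len(names)).sum(axis=1)
        for t, name in enumerate(names):
            counts[name][lo:hi] = per_voxel[:, t]

    maps = ConnectivityMaps(seed_voxels=seed_voxels, counts=counts,
                            waytotal=s, shape=field.shape, affine=field.affine)
    maps.validate()
    return maps
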