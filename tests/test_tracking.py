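"""Streamline engine: deterministic geometry, termination rules, sampling.

The dispersion oracle is an independent single-streamline reference
propagator written as a plain Python loop (no shared code with the batch
engine beyond the field container).
"""
import numpy as np
import pytest

from bgvbq.core import default_affine
from bgvbq.tracking import (FiberField, StreamlineParams, propagate_streamline,
                            track_classify)


def _straight_field(shape=(40, 12, 12), axis=(1.0, 0.0, 0.0),
                    dispersion=0.0, mask=None):
    orientations = np.zeros(shape + (2, 3))
    fractions = np.zeros(shape + (2,))
    if mask is None:
        mask = np.ones(shape, bool)
    orientations[..., 0, :] = np.asarray(axis) / np.linalg.norm(axis)
    fractions[..., 0] = 1.0
    orientations[~mask] = 0.0
    fractions[~mask] = 0.0
    return FiberField(orientations=orientations, fractions=fractions,
                      mask=mask, affine=default_affine(shape),
                      dispersion_deg=dispersion)


def _tube_field(length=40, radius=3.0, pad=6, dispersion=0.0):
    """Straight tube along x embedded in a wider brain mask."""
    shape = (length + 2 * pad, 2 * pad + 2 * int(radius) + 1,
             2 * pad + 2 * int(radius) + 1)
    cy, cz = (shape[1] - 1) / 2, (shape[2] - 1) / 2
    yy, zz = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]),
                         indexing="ij")
    in_tube = (yy - cy) ** 2 + (zz - cz) ** 2 <= radius**2
    orientations = np.zeros(shape + (2, 3))
    fractions = np.zeros(shape + (2,))
    for x in range(pad, pad + length):
        orientations[x, in_tube, 0, :] = (1.0, 0.0, 0.0)
        fractions[x, in_tube, 0] = 1.0
    return FiberField(orientations=orientations, fractions=fractions,
                      mask=np.ones(shape, bool), affine=default_affine(shape),
                      dispersion_deg=dispersion), shape, pad


def _reference_propagate(field, start_vox, direction, params, rng):
    """Independent single-streamline loop (oracle implementation)."""
    pos = np.asarray(start_vox, float).copy()
    prev = np.asarray(direction, float)
    prev = prev / np.linalg.norm(prev)
    shape = field.shape
    sigma = np.deg2rad(field.dispersion_deg)
    for step in range(params.max_steps):
        ijk = tuple(int(np.floor(c + 0.5)) for c in pos)
        if any(i < 0 or i >= s for i, s in zip(ijk, shape)) or not field.mask[ijk]:
            return pos, "mask"
        if step == 0:
            d = prev
        else:
            fr = field.fractions[ijk]
            if fr.sum() <= 0:
                return pos, "no_orientation"
            k = 0 if rng.uniform() * fr.sum() < fr[0] else 1
            d = field.orientations[ijk][k].copy()
            # canonical sign, then Gaussian-angle perturbation
            for comp in d:
                if comp != 0:
                    d = d * np.sign(comp)
                    break
            if sigma > 0:
                theta = abs(rng.normal(0.0, sigma))
                phi = rng.uniform(0.0, 2 * np.pi)
                helper = (np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9
                          else np.array([1.0, 0.0, 0.0]))
                e1 = np.cross(d, helper)
                e1 /= np.linalg.norm(e1)
                e2 = np.cross(d, e1)
                d = (np.cos(theta) * d
                     + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
            if prev @ d < 0:
                d = -d
            if prev @ d < params.curvature_threshold:
                return pos, "curvature"
        pos = pos + params.step * d
        prev = d
    return pos, "max_steps"


class TestPropagation:
    def test_straight_field_gives_straight_ray(self):
        field = _straight_field()
        params = StreamlineParams(step=0.5, rng_seed=0)
        start = (-18.0, 0.0, 0.0)  # world mm; grid spans x in [-19.5, 19.5]
        path, reason = propagate_streamline(field, start, (1, 0, 0), params)
        assert reason == "mask"
        assert np.allclose(path[:, 1], 0.0, atol=1e-9)
        assert np.allclose(path[:, 2], 0.0, atol=1e-9)
        assert path[-1, 0] > 19.0

    def test_ninety_degree_bend_terminates_on_curvature(self):
        shape = (30, 30, 8)
        field = _straight_field(shape)
        # right half of the grid points along +y: an abrupt 90-degree bend
        field.orientations[15:, ..., 0, :] = (0.0, 1.0, 0.0)
        params = StreamlineParams(step=0.5, curvature_threshold=0.2)
        path, reason = propagate_streamline(
            field, (-12.0, 0.0, 0.0), (1, 0, 0), params)
        assert reason == "curvature"
        # stopped at the bend, not at the mask edge
        assert path[-1, 0] == pytest.approx(1.0, abs=1.0)

    def test_start_outside_mask_rejected(self):
        mask = np.ones((40, 12, 12), bool)
        mask[:5] = False
        field = _straight_field(mask=mask)
        with pytest.raises(ValueError, match="outside"):
            propagate_streamline(field, (-18.0, 0.0, 0.0), (1, 0, 0),
                                 StreamlineParams())

    def test_dispersion_exit_fraction_matches_reference(self):
        """Batch engine agrees with the independent loop propagator."""
        field, shape, pad = _tube_field(length=40, radius=3.0, dispersion=10.0)
        params = StreamlineParams(step=0.5, rng_seed=0, max_steps=400)
        start_vox = np.array([pad + 1, (shape[1] - 1) / 2, (shape[2] - 1) / 2])
        x_exit = pad + 40 - 1

        def through(endpos):
            return endpos[0] >= x_exit

        rng = np.random.default_rng(77)
        n_ref = 800
        ref_hits = sum(
            through(_reference_propagate(field, start_vox, (1, 0, 0),
                                         params, rng)[0])
            for _ in range(n_ref))
        p_ref = ref_hits / n_ref

        from bgvbq.tracking import _propagate_batch, _voxel_step
        n_eng = 8000
        pos = np.tile(start_vox, (n_eng, 1)).astype(float)
        dirs = np.tile([1.0, 0.0, 0.0], (n_eng, 1))
        rng2 = np.random.default_rng(78)
        target = np.zeros(shape, dtype=np.int32)
        target[x_exit:, :, :] = 1
        hits, _ = _propagate_batch(field, pos, dirs, _voxel_step(field, params),
                                   rng2, target_ids=target, n_targets=1)
        p_eng = hits[:, 0].mean()
        se = np.sqrt(p_ref * (1 - p_ref) / n_ref + p_eng * (1 - p_eng) / n_eng)
        assert abs(p_eng - p_ref) < 3 * se + 1e-9


class TestClassification:
    def _seed_and_targets(self, shape, pad, length):
        seed = np.zeros(shape, bool)
        cy, cz = (shape[1] - 1) // 2, (shape[2] - 1) // 2
        seed[pad + 1, cy, cz] = True
        target_a = np.zeros(shape, bool)
        target_a[pad + length - 1:, :, :] = True
        return seed, target_a

    def test_single_tube_all_tracts_reach_target(self):
        field, shape, pad = _tube_field(length=40, radius=3.0, dispersion=0.0)
        seed, target_a = self._seed_and_targets(shape, pad, 40)
        target_b = np.zeros(shape, bool)
        target_b[:2, :, :] = False
        target_b[0, 0, 0] = True  # unreachable corner
        params = StreamlineParams(samples_per_voxel=500, rng_seed=1)
        conn = track_classify(field, seed, {"A": target_a, "B": target_b},
                              params)
        assert conn.waytotal == 500
        assert conn.counts["A"][0] == 500
        assert conn.counts["B"][0] == 0

    def test_no_orientations_outside_seed_gives_zero_counts(self):
        shape = (20, 10, 10)
        field = _straight_field(shape)
        field.fractions[:] = 0.0
        field.orientations[:] = 0.0
        seed = np.zeros(shape, bool)
        seed[10, 5, 5] = True
        target = np.zeros(shape, bool)
        target[-1] = True
        conn = track_classify(field, seed, {"T": target},
                              StreamlineParams(samples_per_voxel=100))
        assert conn.counts["T"][0] == 0

    def test_y_branch_fraction_ratio(self):
        """0.7/0.3 fractions at the bifurcation recovered within 3 binomial SE.

        The bifurcation voxel is the seed voxel itself and the step length
        exceeds the voxel size, so every tract makes exactly one orientation
        draw at the branch point — the binomial sampling model the fraction
        semantics promise.
        """
        shape = (40, 45, 21)
        cy, cz = 22, 10
        x0 = 5
        orientations = np.zeros(shape + (2, 3))
        fractions = np.zeros(shape + (2,))
        d_a = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        d_b = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        # bifurcation voxel: both orientations, fractions 0.7 / 0.3
        orientations[x0, cy, cz] = np.stack([d_a, d_b])
        fractions[x0, cy, cz] = (0.7, 0.3)
        # diverging 45-degree branch corridors (wide blocks, disjoint)
        zs = slice(cz - 2, cz + 3)
        for x in range(x0 + 1, shape[0]):
            y_a, y_b = cy + (x - x0), cy - (x - x0)
            orientations[x, max(0, y_a - 2):y_a + 3, zs, 0] = d_a
            fractions[x, max(0, y_a - 2):y_a + 3, zs, 0] = 1.0
            orientations[x, max(0, y_b - 2):y_b + 3, zs, 1] = d_b
            fractions[x, max(0, y_b - 2):y_b + 3, zs, 1] = 0.3
        # resolve corridor overlap near the bifurcation: above the midline
        # the A branch wins, below it the B branch (the midline voxels are
        # unreachable after the first 45-degree step)
        both = (fractions > 0).all(axis=-1)
        both[x0, cy, cz] = False
        yy = np.broadcast_to(np.arange(shape[1])[None, :, None], shape)
        fractions[both & (yy > cy), 1] = 0.0
        fractions[both & (yy < cy), 0] = 0.0
        fractions[both & (yy == cy)] = 0.0
        seed = np.zeros(shape, bool)
        seed[x0, cy, cz] = True
        target_a = np.zeros(shape, bool)
        target_a[:, 41:, :] = True
        target_b = np.zeros(shape, bool)
        target_b[:, :4, :] = True
        field = FiberField(orientations=orientations, fractions=fractions,
                           mask=np.ones(shape, bool),
                           affine=default_affine(shape))
        n = 5000
        conn = track_classify(field, seed, {"A": target_a, "B": target_b},
                              StreamlineParams(samples_per_voxel=n, step=1.5,
                                               rng_seed=4))
        reached = conn.counts["A"][0] + conn.counts["B"][0]
        assert reached > 0.9 * n
        p_hat = conn.counts["A"][0] / reached
        se = np.sqrt(0.7 * 0.3 / reached)
        assert abs(p_hat - 0.7) < 3 * se

    def test_determinism_and_antipodal_invariance(self):
        field, shape, pad = _tube_field(length=30, radius=2.0, dispersion=8.0)
        seed, target = self._seed_and_targets(shape, pad, 30)
        params = StreamlineParams(samples_per_voxel=300, rng_seed=9)
        c1 = track_classify(field, seed, {"T": target}, params)
        c2 = track_classify(field, seed, {"T": target}, params)
        assert c1.counts["T"][0] == c2.counts["T"][0]
        flipped = FiberField(orientations=-field.orientations,
                             fractions=field.fractions, mask=field.mask,
                             affine=field.affine,
                             dispersion_deg=field.dispersion_deg)
        c3 = track_classify(flipped, seed, {"T": target}, params)
        assert c3.counts["T"][0] == c1.counts["T"][0]

    def test_step_halving_stability(self):
        field, shape, pad = _tube_field(length=30, radius=3.0, dispersion=10.0)
        seed, target = self._seed_and_targets(shape, pad, 30)
        n = 4000
        p = {}
        for step in (0.5, 0.25):
            params = StreamlineParams(samples_per_voxel=n, step=step,
                                      rng_seed=11, max_steps=800)
            conn = track_classify(field, seed, {"T": target}, params)
            p[step] = conn.counts["T"][0] / n
        se = np.sqrt(sum(q * (1 - q) / n for q in p.values()))
        assert abs(p[0.5] - p[0.25]) < 3 * se + 1e-9

    def test_counts_bounded_by_waytotal(self, noiseless_field, atlas):
        targets = atlas.masks_by_role("cortical-target")
        conn = track_classify(noiseless_field, atlas.seed_mask, targets,
                              StreamlineParams(samples_per_voxel=50,
                                               rng_seed=2))
        for c in conn.counts.values():
            assert np.all((0 <= c) & (c <= conn.waytotal))

    def test_overlapping_targets_rejected(self):
        field, shape, pad = _tube_field(length=20, radius=2.0)
        seed, target = self._seed_and_targets(shape, pad, 20)
        with pytest.raises(ValueError, match="disjoint"):
            track_classify(field, seed, {"A": target, "B": target},
                           StreamlineParams(samples_per_voxel=10))

    def test_empty_seed_rejected(self):
        field, shape, pad = _tube_field(length=20, radius=2.0)
        with pytest.raises(ValueError, match="seed"):
            track_classify(field, np.zeros(shape, bool),
                           {"A": np.ones(shape, bool)},
                           StreamlineParams(samples_per_voxel=10))
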