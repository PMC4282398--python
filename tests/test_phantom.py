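"""Phantom generator: atlas construction, cohort factor model, forward signals."""
import numpy as np
import pandas as pd
import pytest

from bgvbq.core import ParameterMapSet, default_affine
from bgvbq.phantom import (AtlasSizingError, CohortSpec, FiberFieldSpec,
                           MissingRegionParameter, TractOverlapError,
                           TractSpec, build_atlas, build_fiber_field,
                           default_circuit_loadings, sample_cohort,
                           spgr_exact, spgr_rational,
                           synthesize_weighted_volumes)
from bgvbq.phantom.atlas import SEED_ROLES


class TestAtlas:
    def test_seed_size_per_hemisphere(self, atlas):
        for hemi in ("L", "R"):
            sel = (atlas.regions["role"].isin(SEED_ROLES)
                   & (atlas.regions["hemisphere"] == hemi))
            labels = atlas.regions.loc[sel, "label"].to_numpy()
            n = int(np.isin(atlas.labels, labels).sum())
            assert 30 <= n <= 60

    def test_deterministic(self, atlas):
        again = build_atlas()
        assert np.array_equal(atlas.labels, again.labels)
        pd.testing.assert_frame_equal(atlas.regions, again.regions)

    def test_every_circuit_partner_has_matching_seed(self, atlas):
        seed_circuits = set(
            atlas.regions.loc[atlas.regions["role"].isin(SEED_ROLES), "circuit"])
        partners = atlas.regions[atlas.regions["role"] == "circuit-partner"]
        assert len(partners) > 0
        assert set(partners["circuit"]) <= seed_circuits

    def test_region_table_consistency(self, atlas):
        present = set(np.unique(atlas.labels)) - {0}
        assert present == set(atlas.regions["label"])
        assert not atlas.regions["label"].duplicated().any()

    def test_seed_targets_disjoint(self, atlas):
        targets = atlas.regions.loc[atlas.regions["role"] == "cortical-target",
                                    "label"].to_numpy()
        assert not np.any(atlas.seed_mask & np.isin(atlas.labels, targets))

    @pytest.mark.parametrize("shape", [(20, 56, 48), (30, 30, 30)])
    def test_too_small_grid_raises(self, shape):
        with pytest.raises(AtlasSizingError):
            build_atlas(shape)

    def test_larger_grid_centers_layout(self, atlas):
        big = build_atlas((56, 64, 56))
        # same region voxel counts, shifted position
        for _, row in atlas.regions.iterrows():
            n_small = (atlas.labels == row["label"]).sum()
            n_big = (big.labels == row["label"]).sum()
            assert n_small == n_big


class TestCohortFactorModel:
    def _spec(self, lam, n=101, seed=0, **kw):
        return CohortSpec(n_subjects=n,
                          circuit_loadings=default_circuit_loadings(lam),
                          rng_seed=seed, **kw)

    def test_perfect_loading_gives_unit_correlation(self, atlas):
        cohort = sample_cohort(atlas, self._spec(1.0, seed=3))
        seed = cohort.values("stn_motor_l", "MT")
        partner = cohort.values("putamen_posterior_l", "MT")
        r = np.corrcoef(seed, partner)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_loading_correlation_small(self, atlas):
        """|r| < 0.2 for n=101 in ~95% of seeds under the lambda=0 null."""
        hits = 0
        n_seeds = 200
        for s in range(n_seeds):
            cohort = sample_cohort(atlas, self._spec(0.0, seed=10_000 + s))
            r = np.corrcoef(cohort.values("stn_limbic_l", "R2s"),
                            cohort.values("pallidum_ventral_l", "R2s"))[0, 1]
            hits += abs(r) < 0.2
        assert hits / n_seeds >= 0.93

    def test_factor_covariance_converges(self, atlas):
        """Empirical cross-region correlation -> lam_a * lam_b at large n."""
        lam = 0.7
        cohort = sample_cohort(atlas, self._spec(lam, n=10_000, seed=5))
        r = np.corrcoef(cohort.values("stn_motor_l", "R1"),
                        cohort.values("thalamus_l", "R1"))[0, 1]
        assert r == pytest.approx(lam * lam, abs=0.02)

    def test_population_mean_recovered(self, atlas):
        """Cohort mean of the limbic MT draw stays within 3 SD/sqrt(n)."""
        hits, n_seeds = 0, 100
        mu, sd = 1.1552, 0.1018
        for s in range(n_seeds):
            cohort = sample_cohort(atlas, self._spec(0.7, seed=20_000 + s))
            m = cohort.values("stn_limbic_l", "MT").mean()
            hits += abs(m - mu) <= 3 * sd / np.sqrt(101)
        assert hits / n_seeds >= 0.95

    def test_reproducible_for_fixed_seed(self, atlas):
        a = sample_cohort(atlas, self._spec(0.7, n=5, seed=9))
        b = sample_cohort(atlas, self._spec(0.7, n=5, seed=9))
        pd.testing.assert_frame_equal(a.region_values, b.region_values)
        pd.testing.assert_frame_equal(a.covariates, b.covariates)
        assert np.array_equal(a.render_maps(2).mt, b.render_maps(2).mt)

    def test_missing_region_parameter_names_region(self, atlas):
        spec = self._spec(0.7, n=5)
        spec.region_params = spec.region_params[
            ~((spec.region_params["region"] == "caudate")
              & (spec.region_params["parameter"] == "R1"))]
        with pytest.raises(MissingRegionParameter, match="caudate.*R1"):
            sample_cohort(atlas, spec)

    def test_covariates_in_range(self, atlas):
        cohort = sample_cohort(atlas, self._spec(0.7, n=50, seed=2))
        assert cohort.covariates["age"].between(40, 71).all()
        assert set(cohort.covariates["sex"]) <= {0, 1}


def _uniform_truth(shape=(6, 6, 6), mt=1.2, r1=0.9, r2s=29.0, a=1000.0):
    ones = np.ones(shape)
    return ParameterMapSet(mt=mt * ones, r1=r1 * ones, r2s=r2s * ones,
                           a_app=a * ones, affine=default_affine(shape),
                           mask=np.ones(shape, bool))


class TestForwardSignals:
    def test_echo_ratio_is_pure_r2star_decay(self, protocol):
        truth = _uniform_truth(r2s=30.0)
        vols = synthesize_weighted_volumes(truth, protocol, noise_sd=0.0)
        te = np.asarray(protocol.pdw.te)
        ratio = vols["PDw"][0, 0, 0, -1] / vols["PDw"][0, 0, 0, 0]
        assert ratio == pytest.approx(np.exp(-30.0 * (te[-1] - te[0])), rel=1e-12)

    def test_mtw_with_zero_saturation_equals_rational_pdw_form(self, protocol):
        truth = _uniform_truth(mt=0.0)
        vols = synthesize_weighted_volumes(truth, protocol, noise_sd=0.0)
        c = protocol.mtw
        expected = spgr_rational(1000.0, 0.9, c.flip, c.tr) * np.exp(
            -np.asarray(c.te) * 29.0)
        assert np.allclose(vols["MTw"][0, 0, 0], expected, rtol=1e-12)

    def test_rational_close_to_exact_at_protocol(self, protocol):
        s_rat = spgr_rational(1.0, 1.0, protocol.pdw.flip, protocol.pdw.tr)
        s_ex = spgr_exact(1.0, 1.0, protocol.pdw.flip, protocol.pdw.tr)
        assert abs(s_rat - s_ex) / s_ex < 0.01

    def test_signal_positive_where_amplitude_positive(self, protocol):
        truth = _uniform_truth()
        for mode in ("rational", "exact"):
            vols = synthesize_weighted_volumes(truth, protocol, noise_sd=0.0,
                                               mode=mode)
            for v in vols.values():
                assert np.all(v > 0)

    def test_negative_noise_rejected(self, protocol):
        with pytest.raises(ValueError, match="noise"):
            synthesize_weighted_volumes(_uniform_truth(), protocol,
                                        noise_sd=-1.0)

    def test_nonpositive_b1_rejected(self, protocol):
        from bgvbq.core import B1Map
        b1 = B1Map(f=np.zeros((6, 6, 6)))
        with pytest.raises(ValueError, match="B1"):
            synthesize_weighted_volumes(_uniform_truth(), protocol, b1=b1)


class TestFiberFieldBuilder:
    def test_single_straight_tube_orientations(self, atlas):
        spec = FiberFieldSpec(tracts=[TractSpec(
            source="stn_associative_l", target="superior_frontal",
            waypoints_mm=self._assoc_line(atlas))])
        field = build_fiber_field(atlas, spec)
        has = field.fractions.sum(-1) > 0
        dirs = field.orientations[has]
        dots = np.abs(dirs[:, 0] @ np.array([0.0, 0.0, 1.0]))
        assert np.allclose(dots, 1.0)

    @staticmethod
    def _assoc_line(atlas):
        from bgvbq.core import world_from_voxel
        vox = np.argwhere(atlas.labels == atlas.label_of("stn_associative_l"))
        c = vox.mean(axis=0)
        p0 = world_from_voxel(atlas.affine, np.array([c[0], c[1], c[2] - 1]))[0]
        p1 = world_from_voxel(atlas.affine, np.array([c[0], c[1], c[2] + 22]))[0]
        return np.stack([p0, p1])

    def test_crossing_tubes_occupy_two_slots(self, atlas):
        from bgvbq.core import world_from_voxel

        def w(x, y, z):
            return world_from_voxel(atlas.affine, np.array([x, y, z], float))[0]

        # a vertical tube and a near-horizontal tube crossing it at z = 30,
        # well outside the seed nucleus; fractions 0.7 + 0.3
        spec = FiberFieldSpec(tracts=[
            TractSpec("stn_associative_l", "superior_frontal",
                      np.stack([w(15.5, 26, 19), w(15.5, 26, 42)]),
                      radius_mm=1.0, fraction=0.7),
            TractSpec("stn_motor_l", "superior_frontal",
                      np.stack([w(14.5, 25, 20), w(14.5, 25, 30),
                                w(20, 26, 30), w(20, 26, 42)]),
                      radius_mm=1.0, fraction=0.3),
        ])
        field = build_fiber_field(atlas, spec)
        n_orient = (field.fractions > 0).sum(-1)
        assert n_orient.max() == 2
        both = n_orient == 2
        assert both.sum() >= 1  # crossing voxels exist
        d = field.orientations[both]
        dots = np.abs(np.einsum("ij,ij->i", d[:, 0], d[:, 1]))
        assert np.allclose(dots, 0.0, atol=1e-12)
        assert np.allclose(field.fractions[both].sum(-1), 1.0)

    def test_third_overlap_rejected(self, atlas):
        line = self._assoc_line(atlas)
        tracts = [TractSpec("stn_associative_l", "superior_frontal", line,
                            fraction=0.3) for _ in range(3)]
        with pytest.raises(TractOverlapError):
            build_fiber_field(atlas, FiberFieldSpec(tracts=tracts))

    def test_endpoint_outside_region_rejected(self, atlas):
        line = self._assoc_line(atlas)
        spec = FiberFieldSpec(tracts=[
            TractSpec("stn_motor_l", "superior_frontal", line)])
        with pytest.raises(ValueError, match="source"):
            build_fiber_field(atlas, spec)

    def test_orientations_inside_brain_mask(self, noiseless_field):
        has = noiseless_field.fractions.sum(-1) > 0
        assert np.all(noiseless_field.mask[has])
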