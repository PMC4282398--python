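"""End-to-end phantom studies: the package's reproducible experiments.

Each function runs a complete, seeded experiment at desk scale:

* :func:`derive_parcel` — tractography cohort -> group winner-takes-all
  parcel of the seed nucleus.
* :func:`tissue_recovery_study` — 101-subject cohort: ground-truth maps ->
  multi-echo synthesis (rational mode) -> map fitting -> parcel extraction;
  reports the recovered cohort mean per (subregion, parameter) against the
  generating population parameters.
* :func:`fwe_calibration_study` — family-wise error rate of the max-T
  permutation test under a zero-covariance null.
* :func:`circuit_detection_study` — localization of FWE-surviving voxels to
  within-circuit partner regions under the default factor loading.
* :func:`subregion_ordering_study` — subregion-statistics replicates
  (R2* ordering and the limbic-vs-motor paired test).

The covariance studies sample voxel values directly from the cohort model
(region value + within-region noise) instead of rendering and re-fitting
MRI volumes: estimator exactness is established separately by the recovery
study, and the direct path keeps hundreds of simulated cohorts tractable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PARAMETERS
from .covariance import build_design, extract_seed_values, fit_voxelwise, fwe_correct
from .parcellation import (DEFAULT_CLASS_DEF, ClassMapSet, ParcelMap,
                           aggregate_classes, group_average_parcel, zscore_maps)
from .phantom.atlas import PhantomAtlas, build_atlas
from .phantom.cohort import (Cohort, CohortSpec, _base_name,
                             default_circuit_loadings, sample_cohort,
                             sample_seed_value_table)
from .phantom.fibers import build_fiber_field, default_fiber_spec
from .phantom.signals import synthesize_weighted_volumes
from .protocol import mpm_protocol
from .qmaps import fit_maps
from .roistats import paired_tests, anova_subregions
from .tracking import StreamlineParams, track_classify


def _child_seed(seed: int, *path: int) -> int:
    """Derive an independent integer seed below 2**31 from a root seed."""
    ss = np.random.SeedSequence([int(seed), *map(int, path)])
    return int(ss.generate_state(1)[0] % (2**31))


def derive_parcel(atlas: PhantomAtlas, n_subjects: int = 13,
                  samples_per_voxel: int = 200, dispersion_deg: float = 0.0,
                  seed: int = 0, mode: str = "tripartite") -> ParcelMap:
    """Group-average connectivity parcel from a tractography cohort.

    All phantom subjects share the fiber geometry; subjects differ only in
    the probabilistic sampling stream, mirroring a cohort whose parcels are
    averaged on a common grid.
    """
    field = build_fiber_field(atlas, default_fiber_spec(
        atlas, dispersion_deg=dispersion_deg))
    targets = atlas.masks_by_role("cortical-target")
    subject_maps: list[ClassMapSet] = []
    for s in range(n_subjects):
        params = StreamlineParams(samples_per_voxel=samples_per_voxel,
                                  rng_seed=_child_seed(seed, 11, s))
        conn = track_classify(field, atlas.seed_mask, targets, params)
        subject_maps.append(zscore_maps(aggregate_classes(conn, DEFAULT_CLASS_DEF)))
    return group_average_parcel(subject_maps, mode=mode)


@dataclass
class TissueRecoveryResult:
    cohort_table: pd.DataFrame
    parcel_sizes: dict[str, int]
    recovered: dict[tuple[str, str], float]  # (subregion, parameter) -> mean
    population: dict[tuple[str, str], tuple[float, float]]  # -> (mean, sd)
    n_subjects: int


def tissue_recovery_study(n_subjects: int = 101, seed: int = 0,
                          noise_sd: float = 0.5,
                          n_track_subjects: int = 13,
                          samples_per_voxel: int = 200,
                          ) -> TissueRecoveryResult:
    """Full pipeline recovery of the seed-subregion population parameters."""
    atlas = build_atlas()
    parcel = derive_parcel(atlas, n_subjects=n_track_subjects,
                           samples_per_voxel=samples_per_voxel,
                           dispersion_deg=0.0, seed=_child_seed(seed, 1))
    spec = CohortSpec(n_subjects=n_subjects, rng_seed=_child_seed(seed, 2))
    cohort = sample_cohort(atlas, spec)
    protocol = mpm_protocol()

    def fitted_maps():
        for j in range(n_subjects):
            truth = cohort.render_maps(j)
            rng = np.random.default_rng([spec.rng_seed, 97, j])
            echoes = synthesize_weighted_volumes(
                truth, protocol, noise_sd=noise_sd, mode="rational", rng=rng)
            yield fit_maps(echoes, protocol, mask=truth.mask,
                           affine=atlas.affine)

    table, counts = extract_seed_values(fitted_maps(), parcel,
                                        cohort.covariates)
    recovered, population = {}, {}
    for cls in ("motor", "associative", "limbic"):
        for p in PARAMETERS:
            recovered[(cls, p)] = float(table[f"{cls}_{p}"].mean())
            population[(cls, p)] = spec.lookup(f"stn_{cls}", p)
    return TissueRecoveryResult(cohort_table=table, parcel_sizes=counts,
                                recovered=recovered, population=population,
                                n_subjects=n_subjects)


def _region_name_by_label(atlas: PhantomAtlas) -> dict[int, str]:
    return dict(zip(atlas.regions["label"], atlas.regions["name"]))


def cohort_voxel_matrix(cohort: Cohort, voxels: np.ndarray, parameter: str,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_subjects, V) voxel values at ``voxels`` for one parameter.

    Each voxel carries its region's per-subject value plus independent
    within-region noise, the same generative model ``render_maps`` uses.
    """
    atlas, spec = cohort.atlas, cohort.spec
    labels = atlas.labels[tuple(voxels.T)]
    names = _region_name_by_label(atlas)
    wide = (cohort.region_values[cohort.region_values["parameter"] == parameter]
            .pivot(index="subject", columns="region", values="value"))
    n = cohort.n_subjects
    Y = np.empty((n, len(voxels)))
    for lab in np.unique(labels):
        name = names[int(lab)]
        cols = np.flatnonzero(labels == lab)
        mu, _sd = spec.lookup(_base_name(name), parameter)
        voxel_sd = spec.voxel_sd_frac * abs(mu)
        vals = wide[name].to_numpy()[:, None]
        Y[:, cols] = vals + rng.normal(0.0, voxel_sd, (n, len(cols)))
    return Y


def truth_seed_values(cohort: Cohort, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort table of parcel means computed from ground-truth voxel values."""
    atlas = cohort.atlas
    gt = atlas.seed_ground_truth()
    table = cohort.covariates.copy()
    for value, cls in enumerate(("motor", "associative", "limbic"), start=1):
        voxels = np.argwhere(gt == value)
        for p in PARAMETERS:
            Y = cohort_voxel_matrix(cohort, voxels, p, rng)
            table[f"{cls}_{p}"] = Y.mean(axis=1)
    return table


def _partner_voxels(atlas: PhantomAtlas) -> tuple[np.ndarray, np.ndarray]:
    """Voxel indices of all circuit-partner regions + their circuit labels."""
    partners = atlas.regions[atlas.regions["role"] == "circuit-partner"]
    vox_list, circ_list = [], []
    for _, row in partners.iterrows():
        v = np.argwhere(atlas.labels == row["label"])
        vox_list.append(v)
        circ_list.extend([row["circuit"]] * len(v))
    return np.concatenate(vox_list, axis=0), np.asarray(circ_list)


def _covary_once(cohort: Cohort, voxels: np.ndarray, seed_class: str,
                 parameter: str, n_perm: int, alpha: float,
                 rng: np.random.Generator, perm_seed: int):
    """One seed-based covariance analysis over the given search voxels."""
    table = truth_seed_values(cohort, rng)
    Y = cohort_voxel_matrix(cohort, voxels, parameter, rng)
    X, contrast, names = build_design(table, (seed_class, parameter))
    result = fit_voxelwise({parameter: Y}, {parameter: X}, contrast,
                           voxels=voxels, column_names=names)[parameter]
    return fwe_correct(result, method="permutation", n_perm=n_perm,
                       alpha=alpha, rng_seed=perm_seed)


def fwe_calibration_study(n_cohorts: int = 200, n_subjects: int = 101,
                          n_perm: int = 200, alpha: float = 0.05,
                          seed: int = 0, seed_class: str = "limbic",
                          parameter: str = "R2s") -> dict:
    """Family-wise error rate under the zero-covariance null (lambda = 0)."""
    atlas = build_atlas()
    voxels, _ = _partner_voxels(atlas)
    n_false = 0
    for i in range(n_cohorts):
        spec = CohortSpec(n_subjects=n_subjects,
                          circuit_loadings=default_circuit_loadings(0.0),
                          rng_seed=_child_seed(seed, 21, i))
        cohort = sample_cohort(atlas, spec)
        rng = np.random.default_rng([spec.rng_seed, 5])
        result = _covary_once(cohort, voxels, seed_class, parameter,
                              n_perm, alpha, rng,
                              perm_seed=_child_seed(seed, 22, i))
        if result.surviving.any():
            n_false += 1
    return {"fwe_rate": n_false / n_cohorts, "n_cohorts": n_cohorts,
            "alpha": alpha, "n_perm": n_perm}


def circuit_detection_study(n_subjects: int = 101, n_perm: int = 500,
                            alpha: float = 0.05, seed: int = 0,
                            loading: float = 0.7) -> dict:
    """Localization of surviving voxels under within-circuit covariance.

    Runs all nine (seed class x parameter) analyses over the subcortical
    partner search volume and pools surviving voxels: the fraction inside
    the seed's own circuit partners should be high, the fraction inside
    other circuits' partners near zero.
    """
    atlas = build_atlas()
    voxels, circuits = _partner_voxels(atlas)
    spec = CohortSpec(n_subjects=n_subjects,
                      circuit_loadings=default_circuit_loadings(loading),
                      rng_seed=_child_seed(seed, 31))
    cohort = sample_cohort(atlas, spec)
    n_within = n_cross = n_surviving = 0
    for k, cls in enumerate(("motor", "associative", "limbic")):
        for p in PARAMETERS:
            rng = np.random.default_rng([spec.rng_seed, 6, k])
            result = _covary_once(cohort, voxels, cls, p, n_perm, alpha, rng,
                                  perm_seed=_child_seed(seed, 32, k))
            surv = result.surviving
            n_surviving += int(surv.sum())
            n_within += int((surv & (circuits == cls)).sum())
            n_cross += int((surv & (circuits != cls)).sum())
    return {
        "n_surviving": n_surviving,
        "frac_within_circuit": n_within / n_surviving if n_surviving else np.nan,
        "frac_cross_circuit": n_cross / n_surviving if n_surviving else np.nan,
    }


def subregion_ordering_study(n_replicates: int = 100, n_subjects: int = 101,
                             within_corr: float = 0.5, seed: int = 0,
                             parameter: str = "R2s") -> dict:
    """Replicated subregion statistics from the published population table.

    Each replicate draws per-subject subregion values (common within-subject
    correlation ``within_corr``), checks the limbic > associative > motor
    ordering of the sample means, and runs the ANOVA and the limbic-vs-motor
    paired t-test.
    """
    from .phantom.cohort import DEFAULT_REGION_PARAMS

    means = {s: DEFAULT_REGION_PARAMS[f"stn_{s}"][parameter][0]
             for s in ("motor", "associative", "limbic")}
    sds = {s: DEFAULT_REGION_PARAMS[f"stn_{s}"][parameter][1]
           for s in ("motor", "associative", "limbic")}
    rng = np.random.default_rng([seed, 41])
    n_ordered = 0
    pvals, anova_p = [], []
    for _ in range(n_replicates):
        draws = sample_seed_value_table(means, sds, within_corr,
                                        n_subjects, rng)
        m = draws.mean()
        if m["limbic"] > m["associative"] > m["motor"]:
            n_ordered += 1
        table = draws.rename(columns={s: f"{s}_{parameter}"
                                      for s in draws.columns})
        pt = paired_tests(table, parameter)
        row = pt[pt["pair"] == "limbic vs motor"]
        pvals.append(float(row["p"].iloc[0]))
        _f, ap, _d = anova_subregions(table, parameter)
        anova_p.append(ap)
    return {
        "ordering_fraction": n_ordered / n_replicates,
        "median_limbic_vs_motor_p": float(np.median(pvals)),
        "anova_power": float(np.mean(np.asarray(anova_p) < 0.05)),
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
    }
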