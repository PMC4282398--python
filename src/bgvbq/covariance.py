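"""Seed-based structural covariance of quantitative maps.

Per-subject mean parameter values extracted from the seed parcels act as
regressors of interest in voxel-wise ordinary-least-squares models with age
and sex as nuisance covariates. The three modalities (MT, R1, R2*) can be
fitted separately or stacked into one block-diagonal design — the
block-diagonal fit returns beta estimates identical to the separate fits
(asserted at run time), matching the mass-univariate concatenation approach.

Family-wise error over the search volume is controlled either by
max-statistic permutation of the Freedman-Lane residualized seed regressor
(default) or by Bonferroni; an auxiliary uncorrected p < 0.001 trend mask is
always emitted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import PARAMETERS, ParameterMapSet, world_from_voxel
from .parcellation import ParcelMap


@dataclass
class GLMResult:
    """Voxel-wise OLS fit for one modality with a single contrast of interest."""

    beta: np.ndarray  # (k, V)
    sigma2: np.ndarray  # (V,)
    df: int
    t: np.ndarray  # (V,)
    p: np.ndarray  # (V,) two-tailed
    contrast: np.ndarray
    design: np.ndarray  # (n, k)
    data: np.ndarray  # (n, V)
    column_names: tuple[str, ...]
    voxels: np.ndarray | None = None  # (V, 3) voxel indices
    corrected_p: np.ndarray | None = None
    surviving: np.ndarray | None = None  # (V,) bool
    trend: np.ndarray | None = None  # uncorrected p < 0.001
    threshold: float | None = None
    method: str | None = None


def extract_seed_values(map_sets, parcel: ParcelMap,
                        covariates: pd.DataFrame,
                        hemispheres: str = "pooled",
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-subject mean parameter values over each parcel.

    ``map_sets`` is an iterable of per-subject :class:`ParameterMapSet`
    aligned with the rows of ``covariates``. Returns (cohort table, voxel
    count per parcel column). NaN voxels are excluded from the means;
    hemispheres are pooled by default (``per-side`` splits columns by the
    seed voxel's x position relative to the grid midline).
    """
    if hemispheres not in ("pooled", "per-side"):
        raise ValueError(f"unknown hemispheres mode {hemispheres!r}")
    masks: dict[str, np.ndarray] = {}
    for cls in parcel.class_names:
        m = parcel.mask_of(cls)
        if hemispheres == "pooled":
            masks[cls] = m
        else:
            mid = (parcel.shape[0] - 1) / 2.0
            x = np.arange(parcel.shape[0])[:, None, None]
            masks[f"{cls}_l"] = m & (x < mid)
            masks[f"{cls}_r"] = m & (x >= mid)
    counts = {name: int(m.sum()) for name, m in masks.items()}
    empty = [name for name, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty parcel(s) after masking: {empty}")

    rows = []
    n_sub = None
    for j, maps in enumerate(map_sets):
        row = {}
        for p in PARAMETERS:
            vol = maps.get(p)
            for name, m in masks.items():
                vals = vol[m & maps.mask]
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    raise ValueError(
                        f"parcel {name!r} empty after masking for subject {j}")
                row[f"{name}_{p}"] = float(vals.mean())
        rows.append(row)
        n_sub = j + 1
    if n_sub != len(covariates):
        raise ValueError(f"{n_sub} map sets but {len(covariates)} covariate rows")
    table = pd.concat([covariates.reset_index(drop=True), pd.DataFrame(rows)],
                      axis=1)
    return table, counts


def build_design(cohort: pd.DataFrame, seed: tuple[str, str],
                 ) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Design [seed value, age (centered), sex, intercept] + seed contrast.

    Returns (X, contrast, column names); warns on rank deficiency or a
    large condition number.
    """
    parcel_cls, parameter = seed
    col = f"{parcel_cls}_{parameter}"
    if col not in cohort.columns:
        raise KeyError(f"cohort table lacks seed column {col!r}")
    x_seed = cohort[col].to_numpy(dtype=float)
    age = cohort["age"].to_numpy(dtype=float)
    sex = cohort["sex"].to_numpy(dtype=float)
    X = np.column_stack([x_seed, age - age.mean(), sex, np.ones(len(cohort))])
    names = (col, "age_centered", "sex", "intercept")
    if len(cohort) < X.shape[1] + 1:
        raise ValueError(f"n = {len(cohort)} leaves no residual degrees of "
                         f"freedom for a {X.shape[1]}-column design")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("design matrix is rank deficient; using pseudo-inverse",
                      stacklevel=2)
    cond = np.linalg.cond(X)
    if cond > 1e8:
        warnings.warn(f"design matrix condition number is large ({cond:.3g})",
                      stacklevel=2)
    contrast = np.array([1.0, 0.0, 0.0, 0.0])
    return X, contrast, names


def _tmap(X: np.ndarray, Y: np.ndarray, contrast: np.ndarray,
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS t statistics for one contrast. Returns (t, beta, sigma2, df)."""
    n, k = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (k, V)
    resid = Y - X @ beta
    rank = np.linalg.matrix_rank(X)
    df = n - rank
    sigma2 = (resid**2).sum(axis=0) / df
    # residual variance that is zero up to round-off counts as exactly zero
    zero = sigma2 <= 1e-24 * ((Y**2).mean(axis=0) + 1e-300)
    xtx_inv = pinv @ pinv.T  # == (X'X)^+ for full-rank X
    var_c = float(contrast @ xtx_inv @ contrast)
    se = np.sqrt(sigma2 * var_c)
    num = contrast @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / se
    t[zero] = np.sign(num[zero]) * np.inf
    return t, beta, sigma2, df


def fit_voxelwise(Y: dict[str, np.ndarray], designs: dict[str, np.ndarray],
                  contrast: np.ndarray, structure: str = "separate",
                  voxels: np.ndarray | None = None,
                  column_names: tuple[str, ...] | None = None,
                  ) -> dict[str, GLMResult]:
    """Mass-univariate OLS per modality.

    ``Y[m]`` is (n_subjects, V); ``designs[m]`` is the (n, k) design for
    modality m. ``block-diagonal`` stacks the modalities into one
    block-diagonal system and asserts that the recovered per-modality betas
    equal the separate fits; t statistics always use the per-modality
    residual variance.
    """
    if structure not in ("separate", "block-diagonal"):
        raise ValueError(f"unknown structure {structure!r}")
    names = list(Y)
    results: dict[str, GLMResult] = {}
    betas_sep = {}
    for m in names:
        t, beta, sigma2, df = _tmap(designs[m], Y[m], contrast)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[np.isinf(t)] = 0.0
        betas_sep[m] = beta
        results[m] = GLMResult(beta=beta, sigma2=sigma2, df=df, t=t, p=p,
                               contrast=contrast.copy(), design=designs[m],
                               data=Y[m],
                               column_names=column_names or
                               tuple(f"x{i}" for i in range(designs[m].shape[1])),
                               voxels=voxels)
    if structure == "block-diagonal":
        from scipy.linalg import block_diag

        X_big = block_diag(*[designs[m] for m in names])
        Y_big = np.concatenate([Y[m] for m in names], axis=0)
        beta_big = np.linalg.pinv(X_big) @ Y_big
        k = designs[names[0]].shape[1]
        for i, m in enumerate(names):
            block = beta_big[i * k:(i + 1) * k]
            if not np.allclose(block, betas_sep[m], atol=1e-8):
                raise AssertionError(
                    "block-diagonal betas differ from separate fits")
            results[m].beta = block
    return results


def fwe_correct(result: GLMResult, mask: np.ndarray | None = None,
                method: str = "permutation", n_perm: int = 1000,
                alpha: float = 0.05, rng_seed: int = 0) -> GLMResult:
    """Family-wise-error control over the search volume.

    ``mask`` is a boolean vector over the fitted voxels (default: all).
    Permutation mode builds the max-|t| null by permuting the Freedman-Lane
    residualized seed regressor (nuisance columns held fixed); corrected
    p = (1 + #{maxT_b >= |t|}) / (n_perm + 1). Bonferroni multiplies the
    uncorrected p by the in-mask voxel count. Also emits the auxiliary
    uncorrected p < 0.001 trend mask.
    """
    V = result.t.shape[0]
    if mask is None:
        mask = np.ones(V, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    abs_t = np.abs(result.t)
    corrected = np.ones(V)
    if method == "permutation":
        if n_perm < 100:
            raise ValueError("permutation mode needs n_perm >= 100")
        rng = np.random.default_rng(rng_seed)
        X = result.design
        seed_col = int(np.flatnonzero(result.contrast)[0])
        Z = np.delete(X, seed_col, axis=1)
        x = X[:, seed_col]
        x_res = x - Z @ (np.linalg.pinv(Z) @ x)
        max_null = np.empty(n_perm)
        Y_mask = result.data[:, mask]
        for b in range(n_perm):
            Xp = X.copy()
            Xp[:, seed_col] = rng.permutation(x_res)
            t_b, _, _, _ = _tmap(Xp, Y_mask, result.contrast)
            max_null[b] = np.nanmax(np.abs(t_b))
        exceed = (max_null[None, :] >= abs_t[mask, None]).sum(axis=1)
        corrected[mask] = (1.0 + exceed) / (n_perm + 1.0)
    elif method == "bonferroni":
        v_in = int(mask.sum())
        corrected[mask] = np.minimum(result.p[mask] * v_in, 1.0)
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    corrected = np.maximum(corrected, result.p)  # corrected p >= uncorrected
    result.corrected_p = corrected
    # boundary-inclusive: a voxel exactly at the threshold survives
    result.surviving = mask & (corrected <= alpha * (1.0 + 1e-10))
    result.trend = mask & (result.p < 0.001)
    result.threshold = alpha
    result.method = method
    return result


def report_peaks(result: GLMResult, shape: tuple[int, ...],
                 affine: np.ndarray) -> pd.DataFrame:
    """Cluster table of surviving voxels (26-connectivity components).

    Per cluster: peak |t| voxel in world mm, peak t, cluster size, corrected
    p at the peak.
    """
    if result.surviving is None or result.voxels is None:
        raise ValueError("run fwe_correct on a result fitted with voxel indices")
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(result.voxels[result.surviving].T)] = True
    lab, n_clusters = ndimage.label(vol, structure=np.ones((3, 3, 3)))
    t_vol = np.zeros(shape)
    cp_vol = np.ones(shape)
    t_vol[tuple(result.voxels.T)] = result.t
    if result.corrected_p is not None:
        cp_vol[tuple(result.voxels.T)] = result.corrected_p
    rows = []
    for c in range(1, n_clusters + 1):
        idx = np.argwhere(lab == c)
        tv = np.abs(t_vol[tuple(idx.T)])
        peak = idx[int(np.argmax(tv))]
        world = world_from_voxel(affine, peak.astype(float))[0]
        rows.append({
            "cluster": c, "size": len(idx),
            "x": world[0], "y": world[1], "z": world[2],
            "t": float(t_vol[tuple(peak)]),
            "corrected_p": float(cp_vol[tuple(peak)]),
        })
    rows.sort(key=lambda r: -abs(r["t"]))
    return pd.DataFrame(rows, columns=["cluster", "size", "x", "y", "z",
                                       "t", "corrected_p"])
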