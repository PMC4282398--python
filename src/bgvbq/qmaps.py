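"""Quantitative parameter-map estimation from multi-echo FLASH volumes.

The estimation chain follows the variable-flip-angle multi-parameter
mapping recipe:

1. R2* by log-linear least squares of ln S against TE (default: the eight
   PDw echoes only; optionally one common slope across all contrasts with
   per-contrast intercepts, the ESTATICS-style joint fit), with the
   intercept exponentials serving as TE=0 amplitudes per contrast.
2. R1 and the apparent amplitude A_app from the PDw/T1w TE=0 amplitudes via
   the rational (small-angle, short-TR) dual-flip-angle approximation:

       R1 = 1/2 * (S_t1 a_t1/TR_t1 - S_pd a_pd/TR_pd)
                 / (S_pd/a_pd - S_t1/a_t1)
       A  = S_pd S_t1 (TR_pd a_t1/a_pd - TR_t1 a_pd/a_t1)
                 / (S_t1 TR_pd a_t1 - S_pd TR_t1 a_pd)

   where a_c = f * alpha_c is the B1-corrected effective flip angle.
3. MT saturation (per-excitation fractional saturation, in percent):

       delta = (A a_mt / S_mt - 1) * R1 * TR_mt - a_mt^2 / 2,  MT = 100 delta

   optionally followed by the empirical residual-B1 correction
   delta_corr = delta (1 - 0.4) / (1 - 0.4 f).

Invalid voxels (non-positive signals, vanishing denominators, negative
rates) are set to NaN and removed from the shared mask.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import B1Map, ParameterMapSet
from .protocol import AcquisitionProtocol

CONTRASTS = ("PDw", "T1w", "MTw")


@dataclass
class R2StarFit:
    r2s: np.ndarray
    amplitudes: dict[str, np.ndarray]  # TE=0 amplitude per contrast
    valid: np.ndarray


def _loglinear(echoes: np.ndarray, tes: np.ndarray,
               valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel fit ln S = b0 - R2* TE. Returns (amplitude, r2s)."""
    shape = echoes.shape[:-1]
    x = np.column_stack([np.ones_like(tes), -tes])
    pinv = np.linalg.pinv(x)  # (2, E)
    logs = np.full(echoes.shape, np.nan)
    np.log(echoes, out=logs, where=echoes > 0)
    flat = logs.reshape(-1, len(tes))
    coef = flat @ pinv.T  # (N, 2)
    amp = np.exp(coef[:, 0]).reshape(shape)
    r2s = coef[:, 1].reshape(shape)
    amp[~valid] = np.nan
    r2s[~valid] = np.nan
    return amp, r2s


def fit_r2star(echoes: dict[str, np.ndarray], tes: dict[str, np.ndarray],
               mode: str = "pdw-only", mask: np.ndarray | None = None) -> R2StarFit:
    """Estimate R2* and per-contrast TE=0 amplitudes from multi-echo data.

    ``echoes[c]`` has shape (*grid, n_echoes_c). ``pdw-only`` takes R2* from
    the PDw echoes and extrapolates each contrast to TE=0 with its own
    slope; ``joint`` fits one common R2* with per-contrast intercepts.
    """
    if mode not in ("pdw-only", "joint"):
        raise ValueError(f"unknown R2* mode {mode!r}")
    some = next(iter(echoes.values()))
    grid = some.shape[:-1]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    for c in echoes:
        if len(np.asarray(tes[c])) < 3:
            raise ValueError(f"need >= 3 echoes per contrast, got "
                             f"{len(tes[c])} for {c}")
    valid = mask.copy()
    for c, sig in echoes.items():
        valid &= np.all(sig > 0, axis=-1) | ~mask

    amplitudes, r2s = {}, None
    if mode == "pdw-only":
        for c, sig in echoes.items():
            amp_c, r2s_c = _loglinear(sig, np.asarray(tes[c]), valid)
            amplitudes[c] = amp_c
            if c == "PDw":
                r2s = r2s_c
    else:
        # one common slope, per-contrast intercepts: stacked design
        names = list(echoes)
        te_all, blocks = [], []
        for c in names:
            te_all.append(np.asarray(tes[c]))
            blocks.append(echoes[c])
        n_e = [len(t) for t in te_all]
        x = np.zeros((sum(n_e), len(names) + 1))
        row = 0
        for i, ne in enumerate(n_e):
            x[row:row + ne, i] = 1.0
            x[row:row + ne, -1] = -te_all[i]
            row += ne
        pinv = np.linalg.pinv(x)
        sig = np.concatenate(blocks, axis=-1)
        logs = np.full(sig.shape, np.nan)
        np.log(sig, out=logs, where=sig > 0)
        coef = logs.reshape(-1, sum(n_e)) @ pinv.T
        r2s = coef[:, -1].reshape(grid)
        for i, c in enumerate(names):
            amp = np.exp(coef[:, i]).reshape(grid)
            amp[~valid] = np.nan
            amplitudes[c] = amp
        r2s[~valid] = np.nan
    valid &= np.isfinite(r2s) | ~mask
    return R2StarFit(r2s=r2s, amplitudes=amplitudes, valid=valid & mask)


def fit_r1_a(s_pd: np.ndarray, s_t1: np.ndarray,
             protocol: AcquisitionProtocol, b1: B1Map | None = None,
             mask: np.ndarray | None = None,
             denom_tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rational dual-flip-angle R1 and apparent amplitude.

    Returns (r1, a_app, valid). Voxels with non-positive inputs, vanishing
    denominators, or negative estimates are NaN and excluded from ``valid``.
    """
    if mask is None:
        mask = np.ones(s_pd.shape, dtype=bool)
    f = 1.0 if b1 is None else b1.f
    a_pd = f * protocol.pdw.flip
    a_t1 = f * protocol.t1w.flip
    tr_pd, tr_t1 = protocol.pdw.tr, protocol.t1w.tr

    with np.errstate(divide="ignore", invalid="ignore"):
        num_r1 = 0.5 * (s_t1 * a_t1 / tr_t1 - s_pd * a_pd / tr_pd)
        den_r1 = s_pd / a_pd - s_t1 / a_t1
        r1 = num_r1 / den_r1
        num_a = s_pd * s_t1 * (tr_pd * a_t1 / a_pd - tr_t1 * a_pd / a_t1)
        den_a = s_t1 * tr_pd * a_t1 - s_pd * tr_t1 * a_pd
        a_app = num_a / den_a

    valid = (mask & np.isfinite(s_pd) & np.isfinite(s_t1)
             & (s_pd > 0) & (s_t1 > 0)
             & (np.abs(den_r1) > denom_tol) & (np.abs(den_a) > denom_tol))
    valid &= np.isfinite(r1) & np.isfinite(a_app) & (r1 >= 0)
    r1 = np.where(valid, r1, np.nan)
    a_app = np.where(valid, a_app, np.nan)
    return r1, a_app, valid


def fit_mtsat(s_mt: np.ndarray, a_app: np.ndarray, r1: np.ndarray,
              protocol: AcquisitionProtocol, b1: B1Map | None = None,
              correct_b1: bool = False,
              mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """MT saturation in percent. Returns (mt, valid)."""
    if mask is None:
        mask = np.ones(s_mt.shape, dtype=bool)
    f = 1.0 if b1 is None else b1.f
    a_mt = f * protocol.mtw.flip
    tr_mt = protocol.mtw.tr
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a_app * a_mt / s_mt - 1.0) * r1 * tr_mt - a_mt**2 / 2.0
        if correct_b1:
            delta = delta * (1.0 - 0.4) / (1.0 - 0.4 * f)
    valid = mask & (s_mt > 0) & np.isfinite(delta)
    mt = np.where(valid, 100.0 * delta, np.nan)
    return mt, valid


def fit_maps(echoes: dict[str, np.ndarray], protocol: AcquisitionProtocol,
             b1: B1Map | None = None, mask: np.ndarray | None = None,
             r2s_mode: str = "pdw-only", affine: np.ndarray | None = None,
             correct_b1: bool = False) -> ParameterMapSet:
    """Full estimation chain: echoes -> (MT, R1, R2*, A_app) map set."""
    tes = {c: np.asarray(protocol.contrast(c).te) for c in echoes}
    fit = fit_r2star(echoes, tes, mode=r2s_mode, mask=mask)
    r1, a_app, v1 = fit_r1_a(fit.amplitudes["PDw"], fit.amplitudes["T1w"],
                             protocol, b1=b1, mask=fit.valid)
    mt, v2 = fit_mtsat(fit.amplitudes["MTw"], a_app, r1, protocol, b1=b1,
                       correct_b1=correct_b1, mask=v1)
    valid = fit.valid & v1 & v2
    if affine is None:
        affine = np.eye(4)
    return ParameterMapSet(mt=mt, r1=r1, r2s=fit.r2s, a_app=a_app,
                           affine=affine, mask=valid)


def smooth(volume: np.ndarray, fwhm_mm: float,
           voxel_size=(1.0, 1.0, 1.0),
           weight: np.ndarray | None = None,
           weight_floor: float = 0.05) -> np.ndarray:
    """Isotropic Gaussian smoothing, optionally tissue-weighted.

    Unweighted: plain convolution with sigma = fwhm / (2 sqrt(2 ln 2)) per
    axis (in mm, converted to voxels). Weighted: G(w m)/G(w), with the
    quotient masked to NaN where the smoothed weight falls below
    ``weight_floor`` — the tissue-weighted smoothing used before voxel-wise
    statistics, which avoids blurring across tissue boundaries.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return volume.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / np.asarray(voxel_size)
    if weight is None:
        return ndimage.gaussian_filter(volume.astype(float), sigma=sigma_vox)
    w = np.where(np.isfinite(weight), weight, 0.0)
    m = np.where(np.isfinite(volume) & (w > 0), volume, 0.0)
    gw = ndimage.gaussian_filter(w.astype(float), sigma=sigma_vox)
    gwm = ndimage.gaussian_filter((w * m).astype(float), sigma=sigma_vox)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = gwm / gw
    out[gw < weight_floor] = np.nan
    return out
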