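"""Forward synthesis of multi-echo FLASH volumes from ground-truth maps.

Two steady-state models for the TE=0 amplitude of a spoiled gradient echo at
effective flip angle a = f * alpha_nominal:

* exact:     S0 = A sin(a) (1 - E) / (1 - cos(a) E),  E = exp(-TR * R1)
* rational:  S0 = A a TR R1 / (a^2/2 + TR R1)   (small-angle, short-TR limit)

The MTw contrast always uses the rational form with the per-excitation MT
saturation delta added to the denominator:

    S0 = A a TR R1 / (a^2/2 + TR R1 + delta),  delta = MT(%) / 100.

Echo decay multiplies S0 by exp(-TE * R2*); noise is additive Gaussian.
"""
from __future__ import annotations

import numpy as np

from ..core import B1Map, ParameterMapSet
from ..protocol import AcquisitionProtocol, ContrastProtocol


def spgr_exact(a_app, r1, flip, tr):
    """Exact steady-state SPGR amplitude (no echo decay)."""
    e1 = np.exp(-tr * r1)
    return a_app * np.sin(flip) * (1.0 - e1) / (1.0 - np.cos(flip) * e1)


def spgr_rational(a_app, r1, flip, tr, delta=0.0):
    """Rational small-angle SPGR amplitude, optional MT saturation delta."""
    return a_app * flip * tr * r1 / (flip**2 / 2.0 + tr * r1 + delta)


def contrast_signal(truth: ParameterMapSet, contrast: ContrastProtocol,
                    f=1.0, mode: str = "rational") -> np.ndarray:
    """Noiseless multi-echo signal for one contrast, shape (*grid, n_echoes)."""
    flip = f * contrast.flip
    if contrast.mt_pulse:
        s0 = spgr_rational(truth.a_app, truth.r1, flip, contrast.tr,
                           delta=truth.mt / 100.0)
    elif mode == "rational":
        s0 = spgr_rational(truth.a_app, truth.r1, flip, contrast.tr)
    elif mode == "exact":
        s0 = spgr_exact(truth.a_app, truth.r1, flip, contrast.tr)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'rational' or 'exact'")
    te = np.asarray(contrast.te)
    return s0[..., None] * np.exp(-te * truth.r2s[..., None])


def synthesize_weighted_volumes(truth: ParameterMapSet,
                                protocol: AcquisitionProtocol,
                                b1: B1Map | None = None,
                                noise_sd: float = 0.0,
                                mode: str = "rational",
                                rng: np.random.Generator | None = None,
                                ) -> dict[str, np.ndarray]:
    """Synthesize PDw/T1w/MTw multi-echo volumes from one subject's truth maps.

    Returns {contrast: array of shape (*grid, n_echoes)}. ``noise_sd`` is the
    SD of additive Gaussian noise in signal units (applied inside the brain
    mask; the background stays zero so that synthetic volumes compress well).
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    if b1 is not None:
        b1.validate(truth.mask)
    f = 1.0 if b1 is None else b1.f
    if noise_sd > 0 and rng is None:
        rng = np.random.default_rng(0)
    out = {}
    for name in ("PDw", "T1w", "MTw"):
        sig = contrast_signal(truth, protocol.contrast(name), f=f, mode=mode)
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, sig.shape)
            sig = sig + noise * truth.mask[..., None]
        out[name] = sig
    return out


def uniform_b1(shape, f: float = 1.0) -> B1Map:
    return B1Map(f=np.full(shape, float(f)))


def smooth_b1(shape, rng: np.random.Generator, amplitude: float = 0.1) -> B1Map:
    """Smoothly varying relative flip-angle field in 1 +/- amplitude."""
    from scipy.ndimage import gaussian_filter

    field = gaussian_filter(rng.standard_normal(shape), sigma=max(shape) / 4)
    field = field / max(np.abs(field).max(), 1e-12) * amplitude
    return B1Map(f=1.0 + field)
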