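"""Multi-echo FLASH (spoiled gradient echo) acquisition protocol.

The default protocol is the 3 T multi-parameter mapping (MPM) scheme with
three weightings: predominantly proton-density weighted (PDw, TR 23.7 ms,
flip 6 deg, 8 equidistant echoes 2.2-19.7 ms), T1 weighted (TR 18.7 ms,
flip 20 deg, 6 echoes 2.2-14.7 ms) and magnetization-transfer weighted
(MTw, TR 23.7 ms, flip 6 deg, 6 echoes 2.2-14.7 ms, MT pulse on).

Angles are converted to radians at construction; all downstream formulas use
radians and seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTRASTS = ("PDw", "T1w", "MTw")


@dataclass(frozen=True)
class ContrastProtocol:
    tr: float  # s
    flip: float  # rad, nominal
    te: tuple[float, ...]  # s, strictly increasing
    mt_pulse: bool = False

    def __post_init__(self):
        if not (0.0 < self.flip < np.pi / 2):
            raise ValueError(f"flip angle must be in (0, pi/2) rad, got {self.flip}")
        te = np.asarray(self.te)
        if te.size and np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.tr <= 0:
            raise ValueError("TR must be positive")


@dataclass(frozen=True)
class AcquisitionProtocol:
    pdw: ContrastProtocol
    t1w: ContrastProtocol
    mtw: ContrastProtocol

    def contrast(self, name: str) -> ContrastProtocol:
        try:
            return {"PDw": self.pdw, "T1w": self.t1w, "MTw": self.mtw}[name]
        except KeyError:
            raise KeyError(f"unknown contrast {name!r}; expected PDw, T1w or MTw")

    @classmethod
    def from_degrees(cls, pdw, t1w, mtw) -> "AcquisitionProtocol":
        """Build from dicts with keys tr_ms, flip_deg, te_ms (list), mt_pulse."""

        def conv(d, mt=False):
            return ContrastProtocol(
                tr=d["tr_ms"] * 1e-3,
                flip=np.deg2rad(d["flip_deg"]),
                te=tuple(np.asarray(d["te_ms"]) * 1e-3),
                mt_pulse=d.get("mt_pulse", mt),
            )

        return cls(pdw=conv(pdw), t1w=conv(t1w), mtw=conv(mtw, mt=True))


def equidistant_echoes(first_ms: float, last_ms: float, n: int) -> list[float]:
    return list(np.linspace(first_ms, last_ms, n))


def mpm_protocol() -> AcquisitionProtocol:
    """The default 3 T MPM protocol (see module docstring)."""
    return AcquisitionProtocol.from_degrees(
        pdw={"tr_ms": 23.7, "flip_deg": 6.0, "te_ms": equidistant_echoes(2.2, 19.7, 8)},
        t1w={"tr_ms": 18.7, "flip_deg": 20.0, "te_ms": equidistant_echoes(2.2, 14.7, 6)},
        mtw={"tr_ms": 23.7, "flip_deg": 6.0, "te_ms": equidistant_echoes(2.2, 14.7, 6),
             "mt_pulse": True},
    )


def protocol_from_config(cfg: dict) -> AcquisitionProtocol:
    """Load a protocol from a YAML-style dict with PDw/T1w/MTw sections."""
    return AcquisitionProtocol.from_degrees(cfg["PDw"], cfg["T1w"], cfg["MTw"])
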