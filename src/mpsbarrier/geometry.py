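"""Parametric pillar-array and device geometry.

The interfacial barrier studied here is a single row of circular pillars
separating the cell chamber of a microphysiological system (MPS) from its
media channels.  Two quantities of the barrier matter downstream:

* the porosity (void fraction) of the barrier strip, which sets how much
  cross-section is available for molecular diffusion, and
* the converging–diverging gap profile between two adjacent pillars, which
  is what turns each pore (fenestra) into a capillary burst valve.

All lengths are SI metres internally; use :mod:`mpsbarrier._units` to
convert from device drawings in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "PillarArraySpec",
    "DeviceGeometry",
    "FenestraPath",
    "hydraulic_diameter",
    "porosity",
    "gap_profile",
    "straight_path",
    "pillar_diameter_for_layout",
    "load_preset",
    "available_presets",
]


def hydraulic_diameter(h: float, w: float) -> float:
    """Hydraulic diameter 4A/P = 2hw/(h+w) of an h × w rectangular duct.

    Parameters are the two side lengths in metres.  For the reference
    device a 2 μm × 8 μm fenestra gives D_h = 3.2 μm.
    """
    if h <= 0 or w <= 0:
        raise ValueError(f"duct sides must be positive, got h={h}, w={w}")
    return 2.0 * h * w / (h + w)


def pillar_diameter_for_layout(n_pillars: int, pore_size: float, strip_length: float) -> float:
    """Pillar diameter implied by n pillars and n+1 equal pores spanning the strip.

    Layout convention: ``n·d + (n+1)·g = L_b``.
    """
    if n_pillars < 1:
        raise ValueError("need at least one pillar to derive a diameter")
    d = (strip_length - (n_pillars + 1) * pore_size) / n_pillars
    if d <= 0:
        raise ValueError(
            f"layout infeasible: {n_pillars} pillars with pore {pore_size:g} m "
            f"do not fit in strip length {strip_length:g} m"
        )
    return d


@dataclass(frozen=True)
class PillarArraySpec:
    """One row of circular pillars forming the diffusion barrier.

    Parameters
    ----------
    pore_size:
        Gap g between adjacent pillar walls [m].
    pillar_diameter:
        Pillar diameter d [m].
    n_pillars:
        Number of pillars in the row.
    pillar_height:
        Height h_b of the pillars, i.e. the clearance of the barrier slot [m].
    strip_length:
        Length L_b of the barrier strip along the row [m].
    strip_depth:
        Depth w_b of the strip across the row (crossing direction) [m].
    """

    pore_size: float
    pillar_diameter: float
    n_pillars: int
    pillar_height: float
    strip_length: float
    strip_depth: float

    def __post_init__(self) -> None:
        if self.pore_size <= 0:
            raise ValueError("pore_size must be positive")
        if self.pillar_diameter <= 0:
            raise ValueError("pillar_diameter must be positive")
        if self.pillar_height <= 0:
            raise ValueError("pillar_height must be positive")
        if self.n_pillars < 0:
            raise ValueError("n_pillars must be non-negative")
        occupied = self.n_pillars * self.pillar_diameter + (self.n_pillars + 1) * self.pore_size
        if occupied > self.strip_length * (1 + 1e-12):
            raise ValueError(
                "layout infeasible: n·d + (n+1)·g = "
                f"{occupied:g} m exceeds strip_length {self.strip_length:g} m"
            )
        if self.pillar_diameter > self.strip_depth * (1 + 1e-12):
            raise ValueError(
                f"pillar_diameter {self.pillar_diameter:g} m exceeds "
                f"strip_depth {self.strip_depth:g} m"
            )

    @classmethod
    def from_layout(
        cls,
        n_pillars: int,
        pore_size: float,
        pillar_height: float,
        strip_length: float,
        strip_depth: float,
    ) -> "PillarArraySpec":
        """Derive the pillar diameter from the equal-pore layout convention."""
        d = pillar_diameter_for_layout(n_pillars, pore_size, strip_length)
        return cls(pore_size, d, n_pillars, pillar_height, strip_length, strip_depth)


@dataclass(frozen=True)
class DeviceGeometry:
    """Planar MPS device: cell chamber flanked by media channels via the barrier."""

    chamber_width: float
    chamber_height: float
    chamber_length: float
    media_channel_width: float
    media_channel_height: float
    barrier: PillarArraySpec

    def __post_init__(self) -> None:
        for name in (
            "chamber_width",
            "chamber_height",
            "chamber_length",
            "media_channel_width",
            "media_channel_height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.barrier.pillar_height > self.chamber_height * (1 + 1e-12):
            raise ValueError("barrier pillar_height exceeds chamber_height")


PorosityConvention = Literal["strip", "pillar_band"]


def porosity(spec: PillarArraySpec, convention: PorosityConvention = "strip") -> float:
    """Void fraction of the barrier under one of two area conventions.

    ``strip``
        solid pillar cross-section over the full L_b × w_b strip footprint.
    ``pillar_band``
        same, with the footprint narrowed to the band of width d actually
        occupied by the pillars (L_b × d).

    The value is independent of pillar height: void and total volume both
    scale linearly with h_b.
    """
    n, d = spec.n_pillars, spec.pillar_diameter
    if n == 0:
        return 1.0
    solid = n * math.pi * (d / 2.0) ** 2
    if convention == "strip":
        total = spec.strip_length * spec.strip_depth
    elif convention == "pillar_band":
        total = spec.strip_length * d
    else:
        raise ValueError(f"unknown porosity convention {convention!r}")
    phi = 1.0 - solid / total
    if phi < 0:
        raise ValueError(
            f"convention {convention!r}: pillar cross-section {solid:g} m² exceeds "
            f"footprint {total:g} m² (overlapping pillars?)"
        )
    return phi


@dataclass
class FenestraPath:
    """Sampled gap profile of a single pore along the crossing direction.

    ``s`` runs from −d/2 to +d/2 (pillar entry to exit plane); ``width``
    is the local wall-to-wall gap w(s) and ``divergence_deg`` the signed
    local wall divergence half-plane angle β(s) (negative converging,
    positive diverging).  ``height`` is the out-of-plane slot clearance.
    """

    s: np.ndarray
    width: np.ndarray
    divergence_deg: np.ndarray
    height: float
    length: float
    hydraulic_diameter: float = field(init=False)

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.divergence_deg = np.asarray(self.divergence_deg, dtype=float)
        if self.s.size == 0:
            raise ValueError("empty fenestra path")
        if np.any(self.width <= 0):
            raise ValueError("gap width must be positive everywhere")
        if self.height <= 0:
            raise ValueError("fenestra height must be positive")
        throat = float(self.width.min())
        self.hydraulic_diameter = hydraulic_diameter(self.height, throat)

    @property
    def throat_width(self) -> float:
        return float(self.width.min())


def gap_profile(
    d: float,
    g: float,
    n_samples: int = 401,
    height: float = 2e-6,
) -> FenestraPath:
    """Converging–diverging gap between two adjacent circular pillars.

    At station s ∈ [−d/2, +d/2] along the crossing direction the local gap
    between the circular walls is ``w(s) = (d+g) − 2√((d/2)² − s²)`` with
    throat w(0) = g, and the signed wall divergence angle is
    ``β(s) = arctan(d(w/2)/ds)``.
    """
    if d <= 0 or g <= 0:
        raise ValueError("pillar diameter and pore size must be positive")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    r = d / 2.0
    s = np.linspace(-r, r, n_samples)
    chord = np.sqrt(np.clip(r * r - s * s, 0.0, None))
    w = (d + g) - 2.0 * chord
    # d(w/2)/ds = s/sqrt(r² − s²); ±inf at the entry/exit planes → β = ±90°.
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(chord > 0, s / np.where(chord > 0, chord, 1.0), np.inf * np.sign(s))
    beta = np.degrees(np.arctan(slope))
    beta[0], beta[-1] = -90.0, 90.0
    return FenestraPath(s=s, width=w, divergence_deg=beta, height=height, length=d)


def straight_path(
    width: float,
    height: float,
    length: float,
    n_samples: int = 401,
) -> FenestraPath:
    """Uniform straight microchannel fenestra (β ≡ 0)."""
    if width <= 0 or length <= 0:
        raise ValueError("width and length must be positive")
    s = np.linspace(-length / 2.0, length / 2.0, n_samples)
    return FenestraPath(
        s=s,
        width=np.full_like(s, width),
        divergence_deg=np.zeros_like(s),
        height=height,
        length=length,
    )


def _presets_raw() -> dict:
    text = resources.files("mpsbarrier").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(_presets_raw())


def load_preset(name: str) -> DeviceGeometry:
    """Load a named device preset (dimensions stored in μm in the YAML)."""
    raw = _presets_raw()
    if name not in raw:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(raw)}")
    p = raw[name]
    b = p["barrier"]
    um = 1e-6
    spec = PillarArraySpec(
        pore_size=b["pore_size_um"] * um,
        pillar_diameter=b["pillar_diameter_um"] * um,
        n_pillars=int(b["n_pillars"]),
        pillar_height=b["pillar_height_um"] * um,
        strip_length=b["strip_length_um"] * um,
        strip_depth=b["strip_depth_um"] * um,
    )
    return DeviceGeometry(
        chamber_width=p["chamber_width_um"] * um,
        chamber_height=p["chamber_height_um"] * um,
        chamber_length=p["chamber_length_um"] * um,
        media_channel_width=p["media_channel_width_um"] * um,
        media_channel_height=p["media_channel_height_um"] * um,
        barrier=spec,
    )
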