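"""Seeded generators for the statistical inputs of the tissue analyses.

Three kinds of synthetic data are produced, each emulating a measured
quantity from the cardiac-MPS characterisation campaign:

* single-cell oxygen consumption rates (sOCR), lognormal with mean
  4.67e-17 mol/s (= 4.67e-5 pmol/s) and coefficient of variation 0.69;
* microtissue morphometries (box dimensions, cell density, cell count)
  whose printed means/cv reproduce ~3685 cells at 1.95e14 cell/m³;
* simple four-segment respirometry traces (basal → oligomycin → FCCP →
  rotenone+antimycin) whose per-cell basal rate recovers the sOCR spec.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SOCR_MEAN_MOL_S",
    "SOCR_CV",
    "CELL_DENSITY_MEAN",
    "CELL_DENSITY_CV",
    "TISSUE_DIM_MEANS_UM",
    "TISSUE_DIM_CVS",
    "SOCRDistributionSpec",
    "SyntheticCohort",
    "RespirometryTrace",
    "lognormal_params",
    "sample_socr",
    "sample_tissue_cohort",
    "make_respirometry_fixture",
    "summarize_socr",
]

# Measured study conditions (means and coefficients of variation).
SOCR_MEAN_MOL_S = 4.67e-17  # 4.67e-5 pmol/s per cell
SOCR_CV = 0.69
CELL_DENSITY_MEAN = 1.95e14  # cell/m³
CELL_DENSITY_CV = 0.26
TISSUE_DIM_MEANS_UM = (243.8, 621.6, 124.7)
TISSUE_DIM_CVS = (0.05, 0.28, 0.95)
# cv 0.95 untruncated produces unphysical heights; dims are truncated to
# [0.2, 3] × mean.
DIM_TRUNCATION = (0.2, 3.0)

SEGMENT_ORDER = ("basal", "oligomycin", "FCCP", "rot_aa")


def lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """Exact (μ, σ) of a lognormal with the given mean and cv.

    σ² = ln(1 + cv²),  μ = ln(mean) − σ²/2.
    """
    if mean <= 0 or cv <= 0:
        raise ValueError("mean and cv must be positive")
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class SOCRDistributionSpec:
    """Moment-matched lognormal model of the single-cell OCR distribution."""

    mean: float = SOCR_MEAN_MOL_S  # mol/s per cell
    cv: float = SOCR_CV
    family: str = "lognormal"
    truncation: tuple[float, float] | None = None  # absolute bounds [mol/s]

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.cv <= 0:
            raise ValueError("mean and cv must be positive")
        if self.family != "lognormal":
            raise ValueError(f"unsupported family {self.family!r}")
        if self.truncation is not None and self.truncation[0] >= self.truncation[1]:
            raise ValueError("truncation bounds must be ordered")


def sample_socr(n: int, spec: SOCRDistributionSpec | None = None, seed: int = 0) -> np.ndarray:
    """Draw n sOCR values [mol/s per cell] from the moment-matched lognormal."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SOCRDistributionSpec()
    mu, sigma = lognormal_params(spec.mean, spec.cv)
    rng = np.random.default_rng(seed)
    if spec.truncation is None:
        return rng.lognormal(mu, sigma, size=n)
    lo, hi = spec.truncation
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _truncated_lognormal(
    rng: np.random.Generator, mean: float, cv: float, rel_bounds: tuple[float, float], n: int
) -> np.ndarray:
    mu, sigma = lognormal_params(mean, cv)
    lo, hi = rel_bounds[0] * mean, rel_bounds[1] * mean
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


@dataclass
class SyntheticCohort:
    """Generated tissue morphometry cohort with its provenance recorded."""

    table: pd.DataFrame  # columns: Lx_um, Ly_um, Lz_um, volume_um3, density_per_m3, cell_count
    seed: int
    dim_means_um: tuple[float, float, float] = TISSUE_DIM_MEANS_UM
    dim_cvs: tuple[float, float, float] = TISSUE_DIM_CVS
    density_mean: float = CELL_DENSITY_MEAN
    density_cv: float = CELL_DENSITY_CV
    truncation: tuple[float, float] = DIM_TRUNCATION

    @property
    def mean_density(self) -> float:
        return float(self.table["density_per_m3"].mean())

    @property
    def mean_cell_count(self) -> float:
        return float(self.table["cell_count"].mean())


def sample_tissue_cohort(n: int, seed: int = 0) -> SyntheticCohort:
    """Draw n microtissue morphometries.

    Box dimensions are truncated lognormals at the printed means/cv; cell
    density is lognormal; volume is the product of the dimensions and the
    cell count is density × volume rounded to an integer.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dims = [
        _truncated_lognormal(rng, m, cv, DIM_TRUNCATION, n)
        for m, cv in zip(TISSUE_DIM_MEANS_UM, TISSUE_DIM_CVS)
    ]
    density = rng.lognormal(*lognormal_params(CELL_DENSITY_MEAN, CELL_DENSITY_CV), size=n)
    volume_um3 = dims[0] * dims[1] * dims[2]
    volume_m3 = volume_um3 * 1e-18
    count = np.rint(density * volume_m3).astype(np.int64)
    table = pd.DataFrame(
        {
            "Lx_um": dims[0],
            "Ly_um": dims[1],
            "Lz_um": dims[2],
            "volume_um3": volume_um3,
            "density_per_m3": density,
            "cell_count": count,
        }
    )
    return SyntheticCohort(table=table, seed=seed)


@dataclass
class RespirometryTrace:
    """Piecewise-constant + noise oxygen consumption trace for one well."""

    time_s: np.ndarray
    ocr_pmol_s: np.ndarray
    segment: np.ndarray  # labels from SEGMENT_ORDER, aligned with time_s
    cells_per_well: int
    noise_level: float
    segment_means_pmol_s: dict[str, float] = field(default_factory=dict)


# Post-injection plateaus relative to the basal rate.  Oligomycin blocks
# ATP-synthase-linked respiration, FCCP uncouples to maximal rate, and
# rotenone+antimycin leave only non-mitochondrial consumption.
_SEGMENT_FRACTIONS = {"basal": 1.0, "oligomycin": 0.35, "FCCP": 1.6, "rot_aa": 0.1}
_SEGMENT_DURATION_S = 900.0  # 15 min per segment
_POINTS_PER_SEGMENT = 6


def make_respirometry_fixture(
    n_wells: int,
    seed: int = 0,
    cells_per_well: int = 20_000,
    spec: SOCRDistributionSpec | None = None,
    noise_level: float = 0.03,
) -> list[RespirometryTrace]:
    """Generate per-well respirometry traces consistent with the sOCR spec.

    The basal plateau of each well is an sOCR draw times the number of
    cells, so normalising the basal segment by ``cells_per_well`` recovers
    the single-cell distribution.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if cells_per_well < 1:
        raise ValueError("cells_per_well must be >= 1")
    spec = spec or SOCRDistributionSpec()
    rng = np.random.default_rng(seed)
    socr = sample_socr(n_wells, spec, seed=int(rng.integers(2**31)))
    traces: list[RespirometryTrace] = []
    n_seg = len(SEGMENT_ORDER)
    t = np.concatenate(
        [
            k * _SEGMENT_DURATION_S
            + np.linspace(0.0, _SEGMENT_DURATION_S, _POINTS_PER_SEGMENT, endpoint=False)
            for k in range(n_seg)
        ]
    )
    labels = np.repeat(np.array(SEGMENT_ORDER, dtype=object), _POINTS_PER_SEGMENT)
    for i in range(n_wells):
        basal = socr[i] * cells_per_well / 1e-12  # pmol/s per well
        means = {name: basal * _SEGMENT_FRACTIONS[name] for name in SEGMENT_ORDER}
        plateau = np.repeat([means[name] for name in SEGMENT_ORDER], _POINTS_PER_SEGMENT)
        noise = rng.normal(0.0, noise_level * basal, size=plateau.size) if noise_level > 0 else 0.0
        traces.append(
            RespirometryTrace(
                time_s=t.copy(),
                ocr_pmol_s=plateau + noise,
                segment=labels.copy(),
                cells_per_well=cells_per_well,
                noise_level=noise_level,
                segment_means_pmol_s=means,
            )
        )
    return traces


def summarize_socr(trace: RespirometryTrace) -> float:
    """Per-cell basal OCR of one well in mol/s (basal mean / cells)."""
    if trace.cells_per_well <= 0:
        raise ValueError("cells_per_well must be positive")
    mask = trace.segment == "basal"
    if not np.any(mask):
        raise ValueError("trace has no basal segment")
    basal_pmol_s = float(np.mean(trace.ocr_pmol_s[mask]))
    return basal_pmol_s * 1e-12 / trace.cells_per_well
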