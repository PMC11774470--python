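"""Steady Michaelis–Menten oxygen reaction–diffusion in box microtissues.

The model is the steady state of

    ∂c/∂t = ∇·(D∇c) + R,      R = −sOCR · ρ_c · c/(k_m + c)

on a rectangular tissue domain: oxygen diffuses in from the media through
the four lateral faces (Dirichlet ``c_side``), cannot cross the glass
bottom (no flux), and may enter through the gas-permeable PDMS roof
(Robin flux ``−D ∂c/∂n = k_top (c − c_amb)``, or no-flux).  The tissue
oxygen consumption rate B is the surface integral of the inward oxygen
flux, which at steady state equals the volume integral of the sink.

The population-of-models (PoM) driver re-solves the model for many sOCR
draws to propagate the measured cell-to-cell metabolic variability into
per-geometry distributions of B.

Discretisation: cell-centred finite volumes on a uniform structured grid,
damped Picard iteration on the Michaelis–Menten sink, sparse direct (or
Jacobi-preconditioned CG for large grids) inner solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "TissueGeometry",
    "OxygenParams",
    "SteadyOxygenField",
    "PomResult",
    "solve_oxygen",
    "tissue_ocr",
    "run_pom",
    "DEFAULT_GRID",
    "POM_GRID",
]

DEFAULT_GRID = (32, 64, 16)
#: Coarse grid used by the PoM driver; ~1% of the default grid's cells.
POM_GRID = (12, 24, 10)

_PRESET_DIMS_UM = {
    "V1": (243.8, 621.6, 62.35),
    "V2": (243.8, 621.6, 124.7),
    "V3": (288.0, 950.0, 124.7),
}


@dataclass(frozen=True)
class TissueGeometry:
    """Box tissue domain (metres)."""

    Lx: float
    Ly: float
    Lz: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ValueError("all tissue dimensions must be positive")

    @classmethod
    def preset(cls, label: Literal["V1", "V2", "V3"]) -> "TissueGeometry":
        try:
            dims = _PRESET_DIMS_UM[label]
        except KeyError:
            raise KeyError(f"unknown tissue preset {label!r}; choose from {list(_PRESET_DIMS_UM)}")
        return cls(dims[0] * 1e-6, dims[1] * 1e-6, dims[2] * 1e-6, label)

    @property
    def volume(self) -> float:
        """Box volume [m³]; doubles as the mass proxy for the scaling analysis."""
        return self.Lx * self.Ly * self.Lz


@dataclass(frozen=True)
class OxygenParams:
    """Transport and kinetic parameters of the oxygen model.

    ``tissue_diffusivity`` is not reported for this tissue; 2.0e-9 m²/s is
    a typical soft-tissue value and is deliberately exposed for
    sensitivity analysis.  ``k_top``/``c_amb`` parameterise oxygen supply
    through the PDMS roof.
    """

    tissue_diffusivity: float = 2.0e-9  # m²/s
    michaelis_constant: float = 6.9e-3  # mol/m³
    cell_density: float = 1.95e14  # cell/m³
    side_concentration: float = 0.21  # mol/m³
    top_bc: Literal["robin", "no_flux"] = "robin"
    k_top: float = 1.0e-5  # m/s, only for top_bc="robin"
    c_amb: float = 0.21  # mol/m³, only for top_bc="robin"

    def __post_init__(self) -> None:
        if self.tissue_diffusivity <= 0 or self.michaelis_constant <= 0 or self.cell_density <= 0:
            raise ValueError("D, k_m and ρ_c must be positive")
        if self.side_concentration < 0:
            raise ValueError("side concentration must be non-negative")
        if self.top_bc not in ("robin", "no_flux"):
            raise ValueError(f"unknown top BC {self.top_bc!r}")
        if self.top_bc == "robin" and self.k_top <= 0:
            raise ValueError("k_top must be positive for the Robin top BC")


@dataclass
class SteadyOxygenField:
    """Converged steady oxygen solution on a structured grid."""

    concentration: np.ndarray  # (nx, ny, nz) [mol/m³]
    geometry: TissueGeometry
    params: OxygenParams
    socr: float  # mol/s per cell
    grid: tuple[int, int, int]
    spacing: tuple[float, float, float]
    tissue_ocr_flux: float  # B from the boundary-flux surface integral [mol/s]
    tissue_ocr_volume: float  # B from the volume-integrated sink [mol/s]
    residual: float
    iterations: int
    converged: bool

    @property
    def min_c(self) -> float:
        return float(self.concentration.min())

    @property
    def tissue_ocr(self) -> float:
        return self.tissue_ocr_flux


class _OxygenOperator:
    """Pre-assembled diffusion operator + boundary terms for one (geom, grid)."""

    def __init__(self, geom: TissueGeometry, params: OxygenParams, grid: tuple[int, int, int]):
        nx, ny, nz = grid
        if min(grid) < 2:
            raise ValueError("grid must have at least 2 cells per dimension")
        dx, dy, dz = geom.Lx / nx, geom.Ly / ny, geom.Lz / nz
        D = params.tissue_diffusivity
        n = nx * ny * nz
        vol = dx * dy * dz

        idx = np.arange(n).reshape(nx, ny, nz)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        b = np.zeros(n)
        bc_g = np.zeros(n)  # total conductance to boundary reservoirs, per cell
        bc_c = np.zeros(n)  # conductance-weighted reservoir concentration

        def couple(a: np.ndarray, bb: np.ndarray, g: float) -> None:
            a, bb = a.ravel(), bb.ravel()
            rows.extend((a, bb))
            cols.extend((bb, a))
            vals.extend((np.full(a.size, -g), np.full(a.size, -g)))
            diag[a] += g
            diag[bb] += g

        gx = D * dy * dz / dx
        gy = D * dx * dz / dy
        gz = D * dx * dy / dz
        couple(idx[:-1, :, :], idx[1:, :, :], gx)
        couple(idx[:, :-1, :], idx[:, 1:, :], gy)
        couple(idx[:, :, :-1], idx[:, :, 1:], gz)

        cs = params.side_concentration
        for face, g in (
            (idx[0, :, :], 2 * gx),
            (idx[-1, :, :], 2 * gx),
            (idx[:, 0, :], 2 * gy),
            (idx[:, -1, :], 2 * gy),
        ):
            f = face.ravel()
            diag[f] += g
            b[f] += g * cs
            bc_g[f] += g
            bc_c[f] += g * cs
        if params.top_bc == "robin":
            # series conductance: film k_top and half-cell diffusion
            g_top = dx * dy / (1.0 / params.k_top + dz / (2.0 * D))
            f = idx[:, :, -1].ravel()
            diag[f] += g_top
            b[f] += g_top * params.c_amb
            bc_g[f] += g_top
            bc_c[f] += g_top * params.c_amb
        # bottom (k = 0): no flux — nothing to add

        rows = np.concatenate([np.concatenate(rows), np.arange(n)])
        cols = np.concatenate([np.concatenate(cols), np.arange(n)])
        vals = np.concatenate([np.concatenate(vals), diag])
        self.A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self.b = b
        self.bc_g = bc_g
        self.bc_c = bc_c
        self.vol = vol
        self.grid = grid
        self.spacing = (dx, dy, dz)
        self.geom = geom
        self.params = params
        self.n = n

    def solve(self, A: sp.csr_matrix, rhs: np.ndarray, x0: np.ndarray) -> np.ndarray:
        if self.n <= 5_000:
            return spla.spsolve(A.tocsc(), rhs)
        M = sp.diags(1.0 / A.diagonal())
        x, info = spla.cg(A, rhs, x0=x0, M=M, rtol=1e-10, atol=0.0, maxiter=20 * self.n)
        if info != 0:
            raise RuntimeError(f"inner CG solve failed to converge (info={info})")
        return x


def _nonlinear_residual(op: _OxygenOperator, c: np.ndarray, sink_coeff: float, km: float) -> float:
    r = op.A @ c + sink_coeff * op.vol * c / (km + c) - op.b
    scale = max(np.abs(op.b).max(), 1e-300)
    return float(np.abs(r).max() / scale)


def solve_oxygen(
    geom: TissueGeometry,
    params: OxygenParams | None = None,
    socr: float = 4.67e-17,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    tol: float = 1e-8,
    max_iter: int = 100,
    damping: float = 0.7,
    _op: "_OxygenOperator | None" = None,
    _warm_start: np.ndarray | None = None,
) -> SteadyOxygenField:
    """Solve the steady Michaelis–Menten oxygen model on one tissue box.

    Converges the damped Picard iteration to a relative nonlinear residual
    of ``tol``.  ``socr`` is the single-cell OCR [mol/s]; with ``socr=0``
    the solution is the boundary concentration everywhere and B = 0.
    """
    params = params or OxygenParams()
    if socr < 0:
        raise ValueError("sOCR must be non-negative")
    if min(grid) < 10 and _op is None:
        # contract: at least 10 cells along the shortest dimension unless the
        # caller passes a pre-built operator (internal, e.g. PoM coarse grids)
        raise ValueError(f"grid {grid} has fewer than 10 cells in one dimension")
    op = _op or _OxygenOperator(geom, params, grid)
    km = params.michaelis_constant
    sink_coeff = socr * params.cell_density  # mol/(m³·s) at saturation

    c = (
        _warm_start.copy()
        if _warm_start is not None
        else np.full(op.n, params.side_concentration)
    )
    res_history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        k_lin = sink_coeff * op.vol / (km + c)
        A = op.A + sp.diags(k_lin)
        c_new = op.solve(A, op.b, c)
        c = damping * c_new + (1.0 - damping) * c
        res = _nonlinear_residual(op, c, sink_coeff, km)
        res_history.append(res)
        if res <= tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Picard iteration did not reach tol={tol:g} in {max_iter} iterations; "
            f"residual history tail: {res_history[-5:]}"
        )

    b_flux = float(np.sum(op.bc_c - op.bc_g * c))  # Σ G (c_reservoir − c_cell), inward > 0
    b_vol = float(np.sum(sink_coeff * op.vol * c / (km + c)))
    field = SteadyOxygenField(
        concentration=c.reshape(op.grid),
        geometry=geom,
        params=params,
        socr=socr,
        grid=op.grid,
        spacing=op.spacing,
        tissue_ocr_flux=b_flux,
        tissue_ocr_volume=b_vol,
        residual=res_history[-1],
        iterations=it,
        converged=True,
    )
    return field


def tissue_ocr(field: SteadyOxygenField, check_tol: float = 1e-3) -> float:
    """Tissue OCR B [mol/s]: surface integral of the inward oxygen flux.

    Cross-checked against the volume-integrated Michaelis–Menten sink; the
    two agree to discretisation/solver precision at convergence.
    """
    if not field.converged:
        raise ValueError("tissue_ocr requires a converged field")
    bf, bv = field.tissue_ocr_flux, field.tissue_ocr_volume
    if bv > 0 and abs(bf - bv) / bv > check_tol:
        raise ValueError(
            f"flux-based B={bf:g} and volume-based B={bv:g} disagree by more than "
            f"{check_tol:.1%}: discretisation or convergence issue"
        )
    return bf


@dataclass
class PomResult:
    """Population-of-models output: one row per (geometry, sOCR sample)."""

    table: pd.DataFrame  # columns: geometry, volume_m3, socr, B, min_c
    grid: tuple[int, int, int]
    n_failures: int
    failures: list[tuple[str, float, str]] = field(default_factory=list)

    def distribution_set(self):
        """Per-geometry B samples as a :class:`mpsbarrier.scaling.DistributionSet`."""
        from .scaling import DistributionSet

        groups = []
        for label, sub in self.table.groupby("geometry", sort=False):
            groups.append((float(sub["volume_m3"].iloc[0]), sub["B"].to_numpy(), str(label)))
        return DistributionSet.from_groups(groups)


def run_pom(
    geoms: Sequence[TissueGeometry],
    params: OxygenParams | None = None,
    socr_samples: Iterable[float] = (),
    grid: tuple[int, int, int] = POM_GRID,
    damping: float = 1.0,
) -> PomResult:
    """Solve the oxygen model for every (geometry, sOCR sample) pair.

    Samples are solved in ascending sOCR order with warm starts (the
    steady field varies smoothly with sOCR), then reported in input
    order.  The warm-started Picard iteration is undamped by default —
    the oxygen field stays far from the zero-concentration regime where
    damping is needed.  Individual solve failures are excluded and
    counted.
    """
    params = params or OxygenParams()
    samples = np.asarray(list(socr_samples), dtype=float)
    if samples.size == 0:
        raise ValueError("socr_samples must be non-empty")
    records: list[dict] = []
    failures: list[tuple[str, float, str]] = []
    unique_vals = np.unique(samples)
    for geom in geoms:
        op = _OxygenOperator(geom, params, grid)
        by_value: dict[float, tuple[float, float]] = {}
        warm = None
        for v in unique_vals:  # ascending: the warm start tracks the field
            try:
                fld = solve_oxygen(
                    geom,
                    params,
                    float(v),
                    grid=grid,
                    damping=damping,
                    _op=op,
                    _warm_start=warm,
                )
            except RuntimeError as exc:  # pragma: no cover - pathological inputs
                failures.append((geom.label, float(v), str(exc)))
                continue
            warm = fld.concentration.ravel()
            by_value[float(v)] = (tissue_ocr(fld), fld.min_c)
        for j in range(samples.size):
            if float(samples[j]) in by_value:
                B, mc = by_value[float(samples[j])]
                records.append(
                    {
                        "geometry": geom.label,
                        "volume_m3": geom.volume,
                        "socr": float(samples[j]),
                        "B": B,
                        "min_c": mc,
                    }
                )
    table = pd.DataFrame.from_records(records)
    return PomResult(table=table, grid=grid, n_failures=len(failures), failures=failures)
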