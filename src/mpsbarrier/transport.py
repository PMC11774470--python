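"""Dextran delivery across the barrier: depth-averaged advection–diffusion.

Models the transport of 70 kDa dextran (D = 45.8 μm²/s) injected into the
media channels of the MPS at a set flow rate, across the pillar-array
barrier, into the cell chamber.  The planar (top-view) model carries the
device's depth everywhere: pressure-driven flow uses lubrication
(Hele-Shaw) face conductances ∝ H³/12μ, molecular diffusion uses
depth-linear conductances ∝ H·D, so the shallow barrier slot (height h_b)
throttles convection much harder than diffusion — the mechanism behind
the barrier's diffusion-dominant, tunable transport.

The figure of merit is the diffusion time: the first time the
space-averaged concentration at the middle of the cell chamber reaches a
set fraction (default 0.9) of the feed concentration c0.  Time traces are
also reported non-dimensionally as t* = t·D/L² with the device
characteristic length L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import DeviceGeometry, PillarArraySpec

__all__ = [
    "TransportParams",
    "TransportDomain",
    "FlowField",
    "ConcentrationHistory",
    "rasterize_device",
    "solve_flow",
    "solve_transport",
    "diffusion_time",
    "tunability_sweep",
    "fickian_deviation",
]


@dataclass(frozen=True)
class TransportParams:
    """Solute and operating parameters."""

    diffusivity: float = 45.8e-12  # m²/s, 70 kDa dextran
    inlet_concentration: float = 7.0e-3  # mol/m³
    flow_rate: float = 80e-9 / 60.0  # m³/s (80 μL/min)
    characteristic_length: float = 275e-6  # m, normalisation constant for t*

    def __post_init__(self) -> None:
        for name in ("diffusivity", "inlet_concentration", "characteristic_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flow_rate < 0:
            raise ValueError("flow_rate must be non-negative")


@dataclass
class TransportDomain:
    """Rasterised planar device with a depth map and region masks."""

    dx: float
    depth: np.ndarray  # (nx, ny); 0 ⇒ solid (pillars / walls)
    media: np.ndarray  # bool mask (both media channels)
    chamber: np.ndarray
    barrier: np.ndarray
    center: np.ndarray  # averaging region: central square at chamber mid-length
    inlet: np.ndarray  # cells receiving the imposed inflow (media, y=0 row)
    outlet: np.ndarray  # outlet cells (media, y=end row), p = 0
    device: DeviceGeometry

    @property
    def open_mask(self) -> np.ndarray:
        return self.depth > 0


def rasterize_device(
    device: DeviceGeometry, dx: float = 5e-6, center_side: float = 50e-6
) -> TransportDomain:
    """Rasterise media | barrier | chamber | barrier | media onto a grid.

    x runs across the device, y along the channels; the device length is
    taken from the barrier strip length (the pillar row tiles it exactly).
    Pillars are rasterised as solid disks in each barrier strip.
    """
    b = device.barrier
    L = b.strip_length
    widths = [
        device.media_channel_width,
        b.strip_depth,
        device.chamber_width,
        b.strip_depth,
        device.media_channel_width,
    ]
    W = sum(widths)
    nx = max(int(round(W / dx)), 5)
    ny = max(int(round(L / dx)), 5)
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    X, Y = np.meshgrid(x, y, indexing="ij")

    bounds = np.cumsum([0.0] + widths)
    media = (X < bounds[1]) | (X >= bounds[4])
    barrier = ((X >= bounds[1]) & (X < bounds[2])) | ((X >= bounds[3]) & (X < bounds[4]))
    chamber = (X >= bounds[2]) & (X < bounds[3])

    depth = np.full((nx, ny), device.chamber_height)
    depth[media] = device.media_channel_height
    depth[barrier] = b.pillar_height

    # pillar rows centred in each barrier strip
    d, g, n = b.pillar_diameter, b.pore_size, b.n_pillars
    r2 = (d / 2.0) ** 2
    for xc in (0.5 * (bounds[1] + bounds[2]), 0.5 * (bounds[3] + bounds[4])):
        for k in range(n):
            yc = (k + 1) * g + k * d + d / 2.0
            mask = barrier & ((X - xc) ** 2 + (Y - yc) ** 2 <= r2)
            depth[mask] = 0.0

    xc_mid, yc_mid = 0.5 * (bounds[2] + bounds[3]), L / 2.0
    center = (
        chamber
        & (np.abs(X - xc_mid) <= center_side / 2.0)
        & (np.abs(Y - yc_mid) <= center_side / 2.0)
    )
    inlet = media & (np.arange(ny)[None, :] == 0)
    outlet = media & (np.arange(ny)[None, :] == ny - 1)
    return TransportDomain(
        dx=dx,
        depth=depth,
        media=media & (depth > 0),
        chamber=chamber & (depth > 0),
        barrier=barrier & (depth > 0),
        center=center & (depth > 0),
        inlet=inlet & (depth > 0),
        outlet=outlet & (depth > 0),
        device=device,
    )


@dataclass
class FlowField:
    """Steady depth-averaged flow solution on the device grid."""

    pressure: np.ndarray
    face_flux_x: np.ndarray  # m³/s through x-faces (i→i+1), 0 where closed
    face_flux_y: np.ndarray
    speed: np.ndarray  # cell-centred depth-averaged speed [m/s]
    flow_rate: float
    reynolds: float  # ρ U_max D_h(media) / μ
    domain: TransportDomain


def _face_arrays(open_m: np.ndarray):
    ix = np.argwhere(open_m[:-1] & open_m[1:])
    iy = np.argwhere(open_m[:, :-1] & open_m[:, 1:])
    return ix, iy


def solve_flow(
    domain: TransportDomain,
    Q: float,
    viscosity: float = 1.0e-3,
    density: float = 998.0,
) -> FlowField:
    """Steady low-Reynolds Hele-Shaw flow driven by total inflow Q.

    The inflow is distributed uniformly over the media inlet cells (mass
    flow condition); the media outlet row is held at zero gauge pressure;
    all other boundaries are no-flux walls.  Face conductances scale as
    H³/12μ (lubrication), so the shallow barrier passes very little flow.
    """
    if Q < 0:
        raise ValueError("flow rate must be non-negative")
    open_m = domain.open_mask
    H = domain.depth
    dx = domain.dx
    n = int(open_m.sum())
    idx = -np.ones(open_m.shape, dtype=int)
    idx[open_m] = np.arange(n)

    ix, iy = _face_arrays(open_m)
    fa = np.concatenate([idx[ix[:, 0], ix[:, 1]], idx[iy[:, 0], iy[:, 1]]])
    fb = np.concatenate([idx[ix[:, 0] + 1, ix[:, 1]], idx[iy[:, 0], iy[:, 1] + 1]])
    Ha = np.concatenate([H[ix[:, 0], ix[:, 1]], H[iy[:, 0], iy[:, 1]]])
    Hb = np.concatenate([H[ix[:, 0] + 1, ix[:, 1]], H[iy[:, 0], iy[:, 1] + 1]])
    T = (2.0 / (1.0 / Ha**3 + 1.0 / Hb**3)) / (12.0 * viscosity)

    rhs = np.zeros(n)
    inlet_cells = idx[domain.inlet]
    if Q > 0 and inlet_cells.size == 0:
        raise ValueError("device has no inlet cells")
    if inlet_cells.size:
        rhs[inlet_cells] += Q / inlet_cells.size
    outlet_cells = idx[domain.outlet]
    dirich = np.zeros(n, bool)
    dirich[outlet_cells] = True

    diag = np.zeros(n)
    free_a, free_b = ~dirich[fa], ~dirich[fb]
    np.add.at(diag, fa[free_a], T[free_a])
    np.add.at(diag, fb[free_b], T[free_b])
    both = free_a & free_b
    free = np.flatnonzero(~dirich)
    remap = -np.ones(n, dtype=int)
    remap[free] = np.arange(free.size)
    rows = remap[np.concatenate([fa[both], fb[both], free])]
    cols = remap[np.concatenate([fb[both], fa[both], free])]
    vals = np.concatenate([-T[both], -T[both], np.maximum(diag[free], 1e-300)])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(free.size, free.size))
    p = np.zeros(n)
    if Q > 0:
        p[free] = spla.spsolve(A.tocsc(), rhs[free])

    Qf = T * (p[fa] - p[fb])
    n_xf = ix.shape[0]
    flux_x = np.zeros((open_m.shape[0] - 1, open_m.shape[1]))
    flux_y = np.zeros((open_m.shape[0], open_m.shape[1] - 1))
    flux_x[ix[:, 0], ix[:, 1]] = Qf[:n_xf]
    flux_y[iy[:, 0], iy[:, 1]] = Qf[n_xf:]

    # cell-centred speed from face fluxes
    ux = np.zeros(open_m.shape)
    uy = np.zeros(open_m.shape)
    ux[1:-1] = 0.5 * (flux_x[:-1] + flux_x[1:])
    uy[:, 1:-1] = 0.5 * (flux_y[:, :-1] + flux_y[:, 1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(open_m, np.hypot(ux, uy) / (H * dx + 1e-300), 0.0)
    dev = domain.device
    dh_media = (
        2.0
        * dev.media_channel_width
        * dev.media_channel_height
        / (dev.media_channel_width + dev.media_channel_height)
    )
    u_max = float(speed[domain.media].max()) if Q > 0 else 0.0
    re = density * u_max * dh_media / viscosity
    return FlowField(
        pressure=p,
        face_flux_x=flux_x,
        face_flux_y=flux_y,
        speed=speed,
        flow_rate=Q,
        reynolds=re,
        domain=domain,
    )


@dataclass
class ConcentrationHistory:
    """Transient solution summary: centre-region average trace + metadata."""

    times: np.ndarray
    cbar: np.ndarray  # centre-region average concentration [mol/m³]
    params: TransportParams
    domain: TransportDomain
    c_final: np.ndarray
    snapshots: dict = field(default_factory=dict)

    @property
    def t_star(self) -> np.ndarray:
        L = self.params.characteristic_length
        return self.times * self.params.diffusivity / L**2

    @property
    def c_star(self) -> np.ndarray:
        return self.cbar / self.params.inlet_concentration


def _dt_schedule(t_end: float, dt0: float = 1.0, growth: float = 4.0, per_level: int = 60):
    """Geometric time-step ladder: few distinct dt values → few LU factorisations."""
    out = []
    t, dt = 0.0, dt0
    while t < t_end:
        n = min(per_level, int(np.ceil((t_end - t) / dt)))
        out.append((dt, n))
        t += n * dt
        dt *= growth
    return out


def solve_transport(
    flow: FlowField,
    params: TransportParams,
    t_end: float = 2.0e5,
    hold_media: bool = False,
    zero_advection: bool = False,
    zero_advection_in_chamber: bool = False,
    dt0: float = 1.0,
    scheme: str = "implicit",
) -> ConcentrationHistory:
    """Transient advection–diffusion of the solute on the flow field.

    Inlet cells carry the feed concentration c0 (advective inflow; with
    ``hold_media`` the whole media region is clamped at c0, the
    fast-perfusion limit used for the pure-diffusion oracle).  The outlet
    is an outflow boundary; every other boundary is a no-flux wall.
    First-order upwind advection and central diffusion, integrated with
    backward Euler on a geometric Δt ladder (unconditionally stable,
    monotone).  ``scheme='explicit'`` uses forward Euler instead and
    raises if Δt violates the advective/diffusive stability limit,
    naming the limiting cell.
    """
    domain = flow.domain
    open_m = domain.open_mask
    H = domain.depth
    dx = domain.dx
    D = params.diffusivity
    c0 = params.inlet_concentration
    n = int(open_m.sum())
    idx = -np.ones(open_m.shape, dtype=int)
    idx[open_m] = np.arange(n)
    vol = (H * dx * dx)[open_m]

    ix, iy = _face_arrays(open_m)
    fa = np.concatenate([idx[ix[:, 0], ix[:, 1]], idx[iy[:, 0], iy[:, 1]]])
    fb = np.concatenate([idx[ix[:, 0] + 1, ix[:, 1]], idx[iy[:, 0], iy[:, 1] + 1]])
    Ha = np.concatenate([H[ix[:, 0], ix[:, 1]], H[iy[:, 0], iy[:, 1]]])
    Hb = np.concatenate([H[ix[:, 0] + 1, ix[:, 1]], H[iy[:, 0], iy[:, 1] + 1]])
    Hf = 2.0 / (1.0 / Ha + 1.0 / Hb)  # harmonic depth → diffusive conductance ∝ H·D
    g_diff = D * Hf  # (× dx / dx)

    n_xf = ix.shape[0]
    Qf = np.concatenate(
        [flow.face_flux_x[ix[:, 0], ix[:, 1]], flow.face_flux_y[iy[:, 0], iy[:, 1]]]
    )
    if zero_advection:
        Qf = np.zeros_like(Qf)
    elif zero_advection_in_chamber:
        # pure-diffusion reference for the near-Fickian check: solute is
        # still delivered to the chamber boundary by the flow, but moves
        # inside the chamber by diffusion alone
        ch_flat = domain.chamber[open_m]
        inside_chamber = ch_flat[fa] & ch_flat[fb]
        Qf = np.where(inside_chamber, 0.0, Qf)

    # assemble steady operator A (flux divergence), row = destination cell
    rows, cols, vals = [], [], []
    diag = np.zeros(n)

    def add(r, c_, v):
        rows.append(r)
        cols.append(c_)
        vals.append(v)

    # diffusion
    add(fa, fb, -g_diff)
    add(fb, fa, -g_diff)
    np.add.at(diag, fa, g_diff)
    np.add.at(diag, fb, g_diff)
    # upwind advection
    qp = np.maximum(Qf, 0.0)
    qm = np.minimum(Qf, 0.0)
    np.add.at(diag, fa, qp)
    add(fb, fa, -qp)
    np.add.at(diag, fb, -qm)
    add(fa, fb, qm)

    b = np.zeros(n)
    inlet_cells = idx[domain.inlet]
    outlet_cells = idx[domain.outlet]
    if flow.flow_rate > 0 and not zero_advection:
        q_in = flow.flow_rate / max(inlet_cells.size, 1)
        b[inlet_cells] += q_in * c0  # advective feed
        q_out = flow.flow_rate / max(outlet_cells.size, 1)
        diag[outlet_cells] += q_out  # advective outflow (upwind: cell value)

    clamp = np.zeros(n, bool)
    if hold_media:
        clamp[idx[domain.media]] = True
    elif flow.flow_rate == 0 or zero_advection:
        # no advective feed: hold the inlet row at c0 (Dirichlet source)
        clamp[inlet_cells] = True

    rows = np.concatenate(rows + [np.arange(n)])
    cols = np.concatenate(cols + [np.arange(n)])
    vals = np.concatenate(vals + [diag])
    keepr = ~clamp[rows]
    A = sp.csr_matrix((vals[keepr], (rows[keepr], cols[keepr])), shape=(n, n))
    b = np.where(clamp, 0.0, b)

    c = np.zeros(n)
    c[clamp] = c0
    center_flat = domain.center[open_m]
    center_w = vol[center_flat]

    times = [0.0]
    cbar = [float(np.average(c[center_flat], weights=center_w))]

    if scheme == "explicit":
        # stability bound: vol/(Σ outgoing conductance+flux)
        out_rate = diag.copy()
        dt_lim = np.min(vol / np.maximum(out_rate, 1e-300))
        if dt0 > dt_lim:
            k = int(np.argmin(vol / np.maximum(out_rate, 1e-300)))
            ij = np.argwhere(idx == k)[0]
            raise ValueError(
                f"explicit step dt={dt0:g}s violates the stability limit "
                f"{dt_lim:g}s at cell (i={ij[0]}, j={ij[1]})"
            )
        t = 0.0
        while t < t_end:
            rate = b - A @ c
            c = c + dt0 * rate / vol
            c[clamp] = c0
            t += dt0
            times.append(t)
            cbar.append(float(np.average(c[center_flat], weights=center_w)))
    else:
        t = 0.0
        Ident = sp.diags(vol)
        for dt, nsteps in _dt_schedule(t_end, dt0=dt0):
            M = (Ident / dt + A).tocsc()
            lu = spla.splu(M)
            for _ in range(nsteps):
                rhs = vol * c / dt + b
                c = lu.solve(rhs)
                c[clamp] = c0
                t += dt
                times.append(t)
                cbar.append(float(np.average(c[center_flat], weights=center_w)))
                if t >= t_end:
                    break

    field2d = np.zeros(open_m.shape)
    field2d[open_m] = c
    return ConcentrationHistory(
        times=np.asarray(times),
        cbar=np.asarray(cbar),
        params=params,
        domain=domain,
        c_final=field2d,
    )


def diffusion_time(history: ConcentrationHistory, threshold: float = 0.9) -> float:
    """First time the centre-average reaches ``threshold``·c0 (interpolated)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if threshold == 0.0:
        return 0.0
    target = threshold * history.params.inlet_concentration
    cb, tt = history.cbar, history.times
    above = np.flatnonzero(cb >= target)
    if above.size == 0:
        raise ValueError(
            f"centre concentration only reached {cb.max() / history.params.inlet_concentration:.3f}"
            f"·c0 within t_end={tt[-1]:g}s; threshold {threshold} not attained"
        )
    k = int(above[0])
    if k == 0:
        return float(tt[0])
    frac = (target - cb[k - 1]) / (cb[k] - cb[k - 1])
    return float(tt[k - 1] + frac * (tt[k] - tt[k - 1]))


def tunability_sweep(
    device: DeviceGeometry,
    params: TransportParams,
    heights: list[float] | None = None,
    pore_sizes: list[float] | None = None,
    dx: float = 5e-6,
    t_end: float = 2.0e5,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Diffusion time vs pillar height (or pore size) at fixed flow rate.

    Exactly one of ``heights`` / ``pore_sizes`` is swept; the pillar
    diameter is re-derived from the equal-pore layout when the pore size
    changes.  Returns a table sorted by the swept variable.
    """
    if (heights is None) == (pore_sizes is None):
        raise ValueError("sweep exactly one of heights or pore_sizes")
    rows = []
    sweep = heights if heights is not None else pore_sizes
    if len(sweep) == 0:
        raise ValueError("sweep list is empty")
    for v in sorted(sweep):
        b = device.barrier
        try:
            if heights is not None:
                spec = replace(b, pillar_height=v)
            else:
                spec = PillarArraySpec.from_layout(
                    b.n_pillars, v, b.pillar_height, b.strip_length, b.strip_depth
                )
            dev = replace(device, barrier=spec)
            dom = rasterize_device(dev, dx=dx)
            fl = solve_flow(dom, params.flow_rate)
            hist = solve_transport(fl, params, t_end=t_end)
            t_d = diffusion_time(hist, threshold)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(
                f"sweep configuration {('height' if heights else 'pore')}={v:g} failed: {exc}"
            ) from exc
        rows.append(
            {
                ("pillar_height" if heights is not None else "pore_size"): v,
                "diffusion_time_s": t_d,
                "t_star": t_d * params.diffusivity / params.characteristic_length**2,
            }
        )
    return pd.DataFrame(rows)


def fickian_deviation(history: ConcentrationHistory, reference: ConcentrationHistory) -> float:
    """Max |c̄_adv(t) − c̄_ref(t)|/c0 between an advective run and its
    chamber-advection-free reference on the same grid and time ladder."""
    if history.domain.depth.shape != reference.domain.depth.shape:
        raise ValueError("history and reference were computed on different grids")
    if history.times.shape != reference.times.shape or not np.allclose(
        history.times, reference.times
    ):
        raise ValueError("history and reference use different time ladders")
    c0 = history.params.inlet_concentration
    return float(np.max(np.abs(history.cbar - reference.cbar)) / c0)
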