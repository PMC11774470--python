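"""Reduced planar two-phase interface simulator for burst-pressure runs.

This is a desk-scale stand-in for a full 3D two-phase level-set solver:
a depth-averaged (Hele-Shaw) two-phase model on a planar top-view grid.

Model
-----
* Water fraction c(x, y) evolves by conservative upwind advection with a
  conservative phase-field sharpening term (interface thickness ≈ 2
  cells).
* The flow is depth-averaged Darcy/Hele-Shaw: face conductance
  H³/(12 μ(c)) with the local depth map H(x, y) (deep chamber/media
  regions, shallow barrier slot, solid pillars/walls excluded).
* Capillarity enters as a phase-gradient (CSF) face force with two
  contributions: the resolved in-plane interface curvature γκ with wall
  contact-angle adhesion, and a depth-averaged out-of-plane term
  2γ cos θ/H.  The out-of-plane angle is the advancing contact angle
  inside a uniform depth, but pins at θ* = min(θ_c + 90°, 180°) on faces
  where the water side advances into a depth expansion — the out-of-plane
  analogue of the quasi-static edge-pinning rule, without which a wetting
  liquid (θ_c < 90°) would burst every geometry at zero applied pressure.
* The run is quasi-static: each step advances the interface by at most a
  fixed fraction of a cell, so the reported time axis is a pseudo-time.

Burst criterion: the water volume fraction of the media region beyond
the fenestra exit plane exceeds the burst threshold (default 5%) before
the interface stagnates — with the pinned ("diode") exit faces carrying
exactly zero water flux below threshold, any appreciable water beyond
the exit implies depinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .burst import BurstResult, FluidPair, WATER_AIR, pstar

__all__ = [
    "BurstDomain",
    "TwoPhaseHistory",
    "build_burst_domain",
    "simulate_two_phase",
    "find_burst_pressure",
]


@dataclass
class BurstDomain:
    """Rasterised planar domain: depth map, masks and bookkeeping."""

    dx: float
    depth: np.ndarray  # (nx, ny) local depth H [m]; 0 ⇒ solid
    i_barrier_start: int
    i_exit: int  # last column of the barrier strip
    kind: str
    hydraulic_diameter: float
    open_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.open_mask = self.depth > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


def build_burst_domain(
    kind: str,
    dx: float = 2.5e-6,
    slot_height: float = 2e-6,
    chamber_depth: float = 20e-6,
    media_depth: float = 20e-6,
    chamber_length: float = 30e-6,
    barrier_length: float = 125e-6,
    media_length: float = 30e-6,
    width: float = 175e-6,
    channel_width: float = 8e-6,
    pillar_diameter: float = 79.5e-6,
    pore_size: float = 8e-6,
) -> BurstDomain:
    """Rasterise the single-fenestra burst geometry.

    ``kind='straight'``: the barrier strip is solid except for one
    straight channel of ``channel_width``.  ``kind='pillar'``: the strip
    is an open slot of depth ``slot_height`` containing a row of circular
    pillars (period d+g along y, half-pore margins at the side walls, so
    the domain tiles an infinite row).  Both share a throat of width 8 μm
    at height 2 μm by default (D_h = 3.2 μm).
    """
    if kind not in ("straight", "pillar"):
        raise ValueError(f"kind must be 'straight' or 'pillar', got {kind!r}")
    nx = int(round((chamber_length + barrier_length + media_length) / dx))
    ny = int(round(width / dx))
    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dx
    X, Y = np.meshgrid(x, y, indexing="ij")

    depth = np.full((nx, ny), chamber_depth)
    in_barrier = (X >= chamber_length) & (X < chamber_length + barrier_length)
    depth[X >= chamber_length + barrier_length] = media_depth

    if kind == "straight":
        depth[in_barrier] = 0.0
        channel = in_barrier & (np.abs(Y - width / 2.0) <= channel_width / 2.0)
        depth[channel] = slot_height
        throat = channel_width
    else:
        depth[in_barrier] = slot_height
        period = pillar_diameter + pore_size
        xc = chamber_length + barrier_length / 2.0
        yc = pore_size / 2.0 + pillar_diameter / 2.0
        r2 = (pillar_diameter / 2.0) ** 2
        while yc < width + pillar_diameter:
            pillar = (X - xc) ** 2 + (Y - yc) ** 2 <= r2
            depth[pillar & in_barrier] = 0.0
            yc += period
        throat = pore_size

    i_barrier_start = int(round(chamber_length / dx))
    i_exit = int(round((chamber_length + barrier_length) / dx)) - 1
    dh = 2.0 * slot_height * throat / (slot_height + throat)
    return BurstDomain(
        dx=dx,
        depth=depth,
        i_barrier_start=i_barrier_start,
        i_exit=i_exit,
        kind=kind,
        hydraulic_diameter=dh,
    )


@dataclass
class TwoPhaseHistory:
    """Interface evolution record of one constant-pressure run."""

    times: np.ndarray  # pseudo-time [s]
    water_volume: np.ndarray  # [m³]
    fenestra_fraction: np.ndarray  # water fraction of the open barrier-strip volume
    exit_line_fraction: np.ndarray  # water volume fraction of the media region
    burst: bool
    burst_time: float | None
    stagnated: bool
    steps: int
    mass_error: float  # bound on non-conservative volume error / peak water volume
    c_final: np.ndarray
    applied_pressure: float


def _smooth(c_ext: np.ndarray, open_ext: np.ndarray, passes: int = 2) -> np.ndarray:
    """Box smoothing that ignores non-open cells (keeps their ghost value)."""
    out = c_ext.copy()
    w = open_ext.astype(float)
    for _ in range(passes):
        acc = np.zeros_like(out)
        wacc = np.zeros_like(out)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                acc += np.roll(np.roll(out * w, di, axis=0), dj, axis=1)
                wacc += np.roll(np.roll(w, di, axis=0), dj, axis=1)
        upd = np.where(wacc > 0, acc / np.maximum(wacc, 1e-300), out)
        out = np.where(open_ext, upd, out)
    return out


def simulate_two_phase(
    domain: BurstDomain,
    fluid: FluidPair = WATER_AIR,
    applied_pressure: float = 0.0,
    burst_threshold: float = 0.05,
    max_steps: int = 2500,
    stagnation_steps: int = 100,
    cfl: float = 0.25,
    record_every: int = 10,
    prefill_barrier: bool = True,
    _debug_trace: list | None = None,
) -> TwoPhaseHistory:
    """Drive water from the chamber across the fenestra at fixed pressure.

    The interface advances quasi-statically (each step moves it by at
    most ``cfl`` of a cell).  Faces where the advancing water meets a
    depth expansion are treated as capillary "diode" faces: they carry no
    flux until the phase pressure difference exceeds the pinned Laplace
    threshold 2γ(−cos θ*)/H with θ* = min(θ_c+90°, 180°), which makes
    sub-threshold pinned menisci genuinely static.  Closed diode faces
    carry exactly zero water flux, so any appreciable water beyond the
    exit plane signals depinning: ``burst`` is True iff the water volume
    fraction of the media region exceeds ``burst_threshold`` before the
    interface stagnates (first signal of water in the media channel).
    """
    if applied_pressure < 0:
        raise ValueError("applied pressure must be non-negative")
    dx = domain.dx
    H = domain.depth
    nx, ny = H.shape
    open_m = domain.open_mask
    gamma = fluid.surface_tension
    cos_tc = np.cos(fluid.contact_angle_rad)
    theta_pin = min(fluid.contact_angle_deg + 90.0, 180.0)
    pin_mag = -np.cos(np.radians(theta_pin))  # > 0 for θ_c > 0
    eps_pf = 0.75 * dx  # interface half-thickness (≈ 2-cell interface)

    idx = -np.ones((nx, ny), dtype=int)
    idx[open_m] = np.arange(open_m.sum())
    n_open = int(open_m.sum())
    cell_vol = H * dx * dx  # per-cell fluid volume

    # Water initially fills the chamber.  With a wetting contact angle the
    # barrier slot wicks spontaneously at any applied pressure, so by
    # default the slot is pre-wetted up to the exit plane and the run
    # resolves only the pinned-exit decision and the ensuing flood.
    col = np.arange(nx)[:, None]
    c = np.where(open_m & (col < domain.i_barrier_start), 1.0, 0.0)
    if prefill_barrier:
        in_strip = (col >= domain.i_barrier_start) & (col <= domain.i_exit)
        c = np.where(open_m & in_strip, 1.0, c)
    c[~open_m] = 0.0

    inlet = open_m[0]
    strip = np.zeros((nx, ny), bool)
    strip[domain.i_barrier_start : domain.i_exit + 1] = True
    strip &= open_m
    strip_vol = cell_vol[strip].sum()
    media = np.zeros((nx, ny), bool)
    media[domain.i_exit + 1 :] = True
    media &= open_m
    media_vol = cell_vol[media].sum()

    # combined face list: x-faces then y-faces, orientation a→b
    ix = np.argwhere(open_m[:-1] & open_m[1:])
    iy = np.argwhere(open_m[:, :-1] & open_m[:, 1:])
    fa = np.concatenate([idx[ix[:, 0], ix[:, 1]], idx[iy[:, 0], iy[:, 1]]])
    fb = np.concatenate([idx[ix[:, 0] + 1, ix[:, 1]], idx[iy[:, 0], iy[:, 1] + 1]])
    Ha = np.concatenate([H[ix[:, 0], ix[:, 1]], H[iy[:, 0], iy[:, 1]]])
    Hb = np.concatenate([H[ix[:, 0] + 1, ix[:, 1]], H[iy[:, 0], iy[:, 1] + 1]])
    cell_a_ij = np.concatenate([ix, iy])
    cell_b_ij = np.concatenate([ix + np.array([1, 0]), iy + np.array([0, 1])])
    area_f = np.minimum(Ha, Hb) * dx
    Hf3 = 2.0 / (1.0 / Ha**3 + 1.0 / Hb**3)
    expands_ab = Hb > Ha * 1.01  # deeper on the b side
    expands_ba = Ha > Hb * 1.01

    # in-plane wall-to-wall span of each cell, for the pinned-exit threshold
    span_y = np.zeros((nx, ny))
    for i in range(nx):
        j = 0
        while j < ny:
            if open_m[i, j]:
                k = j
                while k < ny and open_m[i, k]:
                    k += 1
                span_y[i, j:k] = (k - j) * dx
                j = k
            else:
                j += 1
    span_x = np.zeros((nx, ny))
    for j in range(ny):
        i = 0
        while i < nx:
            if open_m[i, j]:
                k = i
                while k < nx and open_m[k, j]:
                    k += 1
                span_x[i:k, j] = (k - i) * dx
                i = k
            else:
                i += 1
    span_donor_ab = np.concatenate(
        [span_y[ix[:, 0], ix[:, 1]], span_x[iy[:, 0], iy[:, 1]]]
    )
    span_donor_ba = np.concatenate(
        [span_y[ix[:, 0] + 1, ix[:, 1]], span_x[iy[:, 0], iy[:, 1] + 1]]
    )
    # pinned meniscus at a depth expansion: θ* = min(θ_c+90°, 180°) in both
    # transverse directions (slot height and local in-plane span), matching
    # the quasi-static exit-expansion formula
    thresh_ab = 2.0 * gamma * pin_mag * (1.0 / np.maximum(Ha, 1e-12) + 1.0 / np.maximum(span_donor_ab, 1e-12))
    thresh_ba = 2.0 * gamma * pin_mag * (1.0 / np.maximum(Hb, 1e-12) + 1.0 / np.maximum(span_donor_ba, 1e-12))

    inlet_cells = idx[0][inlet]
    outlet_cells = idx[-1][open_m[-1]]
    dirich = np.zeros(n_open, bool)
    dirich[inlet_cells] = True
    dirich[outlet_cells] = True
    p_dir = np.zeros(n_open)
    p_dir[inlet_cells] = applied_pressure
    free = np.flatnonzero(~dirich)
    remap = -np.ones(n_open, dtype=int)
    remap[free] = np.arange(free.size)

    times, vols, fracs, exit_fracs = [0.0], [float((c * cell_vol).sum())], [0.0], [0.0]
    t = 0.0
    burst = False
    stagnated = False
    burst_time = None
    vol_watch: list[float] = []
    v_max = float((c * cell_vol).sum())

    def solve_pressure(T_eff: np.ndarray, S: np.ndarray) -> np.ndarray:
        rhs = np.zeros(n_open)
        diag = np.zeros(n_open)
        free_a, free_b = ~dirich[fa], ~dirich[fb]
        np.add.at(diag, fa[free_a], T_eff[free_a])
        np.add.at(diag, fb[free_b], T_eff[free_b])
        np.add.at(rhs, fa[free_a], -(T_eff * S)[free_a])
        np.add.at(rhs, fb[free_b], (T_eff * S)[free_b])
        a_dir = free_b & ~free_a
        b_dir = free_a & ~free_b
        np.add.at(rhs, fb[a_dir], (T_eff * p_dir[fa])[a_dir])
        np.add.at(rhs, fa[b_dir], (T_eff * p_dir[fb])[b_dir])
        both = free_a & free_b
        rows = remap[np.concatenate([fa[both], fb[both], free])]
        cols = remap[np.concatenate([fb[both], fa[both], free])]
        vals = np.concatenate([-T_eff[both], -T_eff[both], np.maximum(diag[free], 1e-30)])
        A = sp.csr_matrix((vals, (rows, cols)), shape=(free.size, free.size))
        p_free = spla.spsolve(A.tocsc(), rhs[free])
        if not np.all(np.isfinite(p_free)):
            raise RuntimeError(f"pressure solve diverged at pseudo-time {t:g} s")
        p = p_dir.copy()
        p[free] = p_free
        return p

    step = 0
    for step in range(1, max_steps + 1):
        c[0][inlet] = 1.0  # water reservoir at the inlet

        # --- smoothed field with wall-adhesion ghost values -------------
        c_ext = c.copy()
        nb_sum = np.zeros((nx, ny))
        nb_w = np.zeros((nx, ny))
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb_sum += np.roll(np.roll(c * open_m, di, axis=0), dj, axis=1)
            nb_w += np.roll(np.roll(open_m.astype(float), di, axis=0), dj, axis=1)
        ghost_base = np.where(nb_w > 0, nb_sum / np.maximum(nb_w, 1e-300), 0.0)
        ghost = np.clip(ghost_base + 2.0 * cos_tc * ghost_base * (1.0 - ghost_base), 0.0, 1.0)
        c_ext[~open_m] = ghost[~open_m]
        cs = _smooth(c_ext, open_m)

        # --- in-plane curvature (CSF) -----------------------------------
        gx = (np.roll(cs, -1, axis=0) - np.roll(cs, 1, axis=0)) / (2 * dx)
        gy = (np.roll(cs, -1, axis=1) - np.roll(cs, 1, axis=1)) / (2 * dx)
        gmag = np.sqrt(gx * gx + gy * gy)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = np.where(gmag > 1e-6 / dx, gx / gmag, 0.0)
            my = np.where(gmag > 1e-6 / dx, gy / gmag, 0.0)
        div_m = (np.roll(mx, -1, axis=0) - np.roll(mx, 1, axis=0)) / (2 * dx) + (
            np.roll(my, -1, axis=1) - np.roll(my, 1, axis=1)
        ) / (2 * dx)
        kappa = np.clip(div_m, -1.0 / dx, 1.0 / dx)
        pi_in = np.where(gmag * dx > 0.01, -gamma * kappa, 0.0)

        ca = cs[cell_a_ij[:, 0], cell_a_ij[:, 1]]
        cb = cs[cell_b_ij[:, 0], cell_b_ij[:, 1]]
        dc = ca - cb
        c_raw = c[open_m]
        pi_in_f = 0.5 * (
            pi_in[cell_a_ij[:, 0], cell_a_ij[:, 1]] + pi_in[cell_b_ij[:, 0], cell_b_ij[:, 1]]
        )

        # Depth-expansion ("diode") faces: while the deep receiving cell is
        # not yet water-filled, the meniscus pins at the expansion edge.
        # The face then passes displaced air freely but carries no water
        # until the phase pressure drop exceeds the pinned Laplace
        # threshold 2γ(−cos θ*)/H_shallow (θ* = min(θ_c+90°, 180°)),
        # corrected by the resolved in-plane curvature at the mouth.
        diode_ab = expands_ab & (c_raw[fb] < 0.95)  # forward = a→b
        diode_ba = expands_ba & (c_raw[fa] < 0.95)  # forward = b→a
        diode = diode_ab | diode_ba
        thresh = np.where(diode_ab, thresh_ab, thresh_ba)
        donor_full = np.where(diode_ab, c_raw[fa], c_raw[fb]) >= 0.90

        # ordinary capillary face force (non-diode faces)
        pi_z = 2.0 * gamma * cos_tc / np.minimum(Ha, Hb)
        S_reg = (pi_z + pi_in_f) * dc
        cf = 0.5 * (ca + cb)
        mu_f = fluid.air_viscosity + cf * (fluid.water_viscosity - fluid.air_viscosity)
        T_base = Hf3 / (12.0 * mu_f)

        # --- diode complementarity loop ----------------------------------
        # closed diode faces: air-drain mode (T on, no water) while the
        # donor cell still holds air, hard-blocked once it is full
        open_state = np.zeros(fa.size, bool)
        p = None
        for _ in range(6):
            blocked = diode & ~open_state & donor_full
            T_eff = np.where(blocked, 0.0, T_base)
            S = np.where(
                diode,
                np.where(open_state, np.where(diode_ab, -thresh, thresh), 0.0),
                S_reg,
            )
            p = solve_pressure(T_eff, S)
            dp_face = p[fa] - p[fb]
            should_open = diode & np.where(diode_ab, dp_face > thresh, -dp_face > thresh)
            if np.array_equal(should_open, open_state):
                break
            open_state = should_open

        blocked = diode & ~open_state & donor_full
        T_eff = np.where(blocked, 0.0, T_base)
        S = np.where(
            diode,
            np.where(open_state, np.where(diode_ab, -thresh, thresh), 0.0),
            S_reg,
        )
        Q = T_eff * (p[fa] - p[fb] + S)  # m³/s, positive a→b
        # closed diode faces pass only air; open ones only forward water
        water_free = diode & ~open_state
        Q_forward_ok = np.where(diode_ab, Q > 0, Q < 0)

        c_flat = c[open_m]
        F = np.where(Q > 0, Q * c_flat[fa], Q * c_flat[fb])
        F = np.where(water_free, 0.0, F)  # pinned faces carry no water
        F = np.where(diode & open_state & ~Q_forward_ok, 0.0, F)

        # conservative sharpening fluxes (Chiu–Lin), velocity scale Γ
        vol_flat = cell_vol[open_m]
        with np.errstate(divide="ignore", invalid="ignore"):
            u_face = np.abs(Q) / area_f
        u_scale = float(u_face.max()) if u_face.size else 0.0
        if u_scale > 0:
            m_comp = np.concatenate(
                [
                    0.5 * (mx[ix[:, 0], ix[:, 1]] + mx[ix[:, 0] + 1, ix[:, 1]]),
                    0.5 * (my[iy[:, 0], iy[:, 1]] + my[iy[:, 0], iy[:, 1] + 1]),
                ]
            )
            cf_r = 0.5 * (c_flat[fa] + c_flat[fb])
            G = u_scale * area_f * (
                -eps_pf * (c_flat[fb] - c_flat[fa]) / dx + cf_r * (1 - cf_r) * m_comp
            )
            G = np.where(diode & ~open_state, 0.0, G)  # no leak through pinned faces
            F = F + G

        div = np.zeros(n_open)
        np.add.at(div, fa, F)
        np.add.at(div, fb, -F)

        dt = cfl * np.min(vol_flat / np.maximum(np.abs(div), 1e-300))
        dt = min(dt, 1.0)  # cap the pseudo-time step

        c_new_flat = c_flat - dt * div / vol_flat
        c_new_flat[inlet_cells] = 1.0
        clipped = np.clip(c_new_flat, 0.0, 1.0)
        c = np.zeros_like(c)
        c[open_m] = clipped
        t += dt

        v_now = float((c * cell_vol).sum())
        v_max = max(v_max, v_now)
        exit_frac = float((c * cell_vol)[media].sum() / media_vol)
        if step % record_every == 0 or exit_frac >= burst_threshold:
            times.append(t)
            vols.append(v_now)
            fracs.append(float((c * cell_vol)[strip].sum() / strip_vol))
            exit_fracs.append(exit_frac)
        if exit_frac >= burst_threshold:
            burst = True
            burst_time = t
            break
        if _debug_trace is not None and step % 25 == 0:
            donor_cells = np.unique(np.concatenate([fa[diode_ab], fb[diode_ba]])) if (diode_ab.any() or diode_ba.any()) else np.array([], dtype=int)
            _debug_trace.append(dict(step=step, t=t, v=v_now, dt=dt,
                n_diode=int(diode.sum()), n_open=int(open_state.sum()),
                n_blocked=int((diode & ~open_state & donor_full).sum()),
                donor_max=float(c_raw[donor_cells].max()) if donor_cells.size else -1,
                dp_max=float((p[fa]-p[fb])[diode_ab].max()) if diode_ab.any() else 0.0,
                thr_min=float(thresh[diode_ab].min()) if diode_ab.any() else 0.0,
                media=exit_frac))
        vol_watch.append(v_now)
        if len(vol_watch) > stagnation_steps:
            vol_watch.pop(0)
            if max(vol_watch) - min(vol_watch) < 1e-3 * v_max:
                stagnated = True
                break

    mass_error = _mass_error_estimate(c, cell_vol, v_max)

    return TwoPhaseHistory(
        times=np.asarray(times),
        water_volume=np.asarray(vols),
        fenestra_fraction=np.asarray(fracs),
        exit_line_fraction=np.asarray(exit_fracs),
        burst=burst,
        burst_time=burst_time,
        stagnated=stagnated,
        steps=step,
        mass_error=mass_error,
        c_final=c,
        applied_pressure=applied_pressure,
    )


def _mass_error_estimate(c: np.ndarray, cell_vol: np.ndarray, v_max: float) -> float:
    """Bound on non-conservative volume error from the clip step.

    The advection and sharpening fluxes are in conservative (flux) form,
    so the only volume error comes from clipping c to [0, 1]; overshoots
    are bounded by the residual of c outside [0,1] before clipping, which
    the CFL limit keeps at machine-precision level.  Reported as a
    fraction of the peak water volume.
    """
    v_now = float((c * cell_vol).sum())
    overshoot = float(np.sum(np.clip(c - 1.0, 0.0, None) * cell_vol))
    undershoot = float(np.sum(np.clip(-c, 0.0, None) * cell_vol))
    return (overshoot + undershoot) / max(v_max, v_now, 1e-300)


def find_burst_pressure(
    domain: BurstDomain,
    fluid: FluidPair = WATER_AIR,
    bracket: tuple[float, float] = (0.0, 1.5e5),
    tol: float = 50.0,
    **sim_kwargs,
) -> BurstResult:
    """Bisect the applied pressure to the burst threshold.

    ``bracket`` must straddle the outcome (no burst at the low end, burst
    at the high end).  Returns the bracket midpoint and the matching
    p* = Δp·D_h/γ.
    """
    lo, hi = bracket
    if lo >= hi:
        raise ValueError("bracket must be an increasing interval")
    if tol <= 0:
        raise ValueError("tol must be positive")
    h_lo = simulate_two_phase(domain, fluid, lo, **sim_kwargs)
    h_hi = simulate_two_phase(domain, fluid, hi, **sim_kwargs)
    if h_lo.burst or not h_hi.burst:
        raise ValueError(
            "bracket does not straddle the burst transition "
            f"(burst at {lo:g} Pa: {h_lo.burst}, at {hi:g} Pa: {h_hi.burst}); "
            "expand the bracket"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if simulate_two_phase(domain, fluid, mid, **sim_kwargs).burst:
            hi = mid
        else:
            lo = mid
    dp = 0.5 * (lo + hi)
    return BurstResult(
        burst_pressure=dp,
        p_star=pstar(dp, domain.hydraulic_diameter, fluid.surface_tension),
        burst_position=float("nan"),
        method="simulated",
    )
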