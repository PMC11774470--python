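"""Transport: flow continuity, diffusion oracles, tunability, Fickian checks."""

import numpy as np
import pytest

from mpsbarrier import geometry as G
from mpsbarrier import transport as T

DX = 5e-6
UL_MIN = 1e-9 / 60.0  # m³/s per μL/min


@pytest.fixture(scope="module")
def small_domain(small_device):
    return T.rasterize_device(small_device, dx=DX)


@pytest.fixture(scope="module")
def small_flow(small_domain):
    return T.solve_flow(small_domain, 80 * UL_MIN)


class TestSolveFlow:
    def test_zero_flow_is_quiescent(self, small_domain):
        fl = T.solve_flow(small_domain, 0.0)
        assert np.all(fl.speed == 0.0)
        assert fl.reynolds == 0.0

    def test_continuity_across_sections(self, small_flow):
        """Net volumetric flux through every y-cross-section equals Q."""
        Q = small_flow.flow_rate
        ny = small_flow.domain.depth.shape[1]
        for j in (1, ny // 2, ny - 2):
            assert small_flow.face_flux_y[:, j].sum() == pytest.approx(Q, rel=1e-6)

    def test_laminar_regime(self, small_flow):
        assert 0 < small_flow.reynolds < 2000

    def test_barrier_throttles_flow(self, small_flow):
        dom = small_flow.domain
        assert small_flow.speed[dom.barrier].max() < 1e-2 * small_flow.speed[dom.media].max()

    def test_negative_rate_rejected(self, small_domain):
        with pytest.raises(ValueError):
            T.solve_flow(small_domain, -1.0)


class TestSolveTransport:
    def test_equilibrates_to_feed_concentration(self, small_flow):
        par = T.TransportParams(flow_rate=80 * UL_MIN)
        hist = T.solve_transport(small_flow, par, t_end=4e5)
        assert hist.cbar[-1] == pytest.approx(par.inlet_concentration, rel=0.01)

    def test_maximum_principle(self, small_flow):
        par = T.TransportParams(flow_rate=80 * UL_MIN)
        hist = T.solve_transport(small_flow, par, t_end=5e4)
        c0 = par.inlet_concentration
        assert hist.c_final.min() >= -1e-2 * c0
        assert hist.c_final.max() <= 1.01 * c0
        assert np.all(np.diff(hist.cbar) >= -1e-9 * c0)  # monotone approach

    def test_solute_mass_matches_equilibrium(self, small_domain):
        """At t → ∞ with the media clamped at c0, total mass → c0·V (±1%)."""
        fl = T.solve_flow(small_domain, 0.0)
        par = T.TransportParams(flow_rate=0.0)
        hist = T.solve_transport(fl, par, t_end=6e5, hold_media=True, zero_advection=True)
        vol = small_domain.depth * small_domain.dx**2
        mass = float((hist.c_final * vol).sum())
        expected = par.inlet_concentration * float(vol[small_domain.open_mask].sum())
        assert mass == pytest.approx(expected, rel=0.01)

    def test_explicit_scheme_cfl_guard(self, small_flow):
        par = T.TransportParams(flow_rate=80 * UL_MIN)
        with pytest.raises(ValueError, match="cell"):
            T.solve_transport(small_flow, par, t_end=10.0, scheme="explicit", dt0=10.0)


class TestDiffusionTime:
    def test_zero_threshold_is_zero(self, small_flow):
        par = T.TransportParams(flow_rate=80 * UL_MIN)
        hist = T.solve_transport(small_flow, par, t_end=1e3)
        assert T.diffusion_time(hist, 0.0) == 0.0

    def test_threshold_monotone(self, small_flow):
        par = T.TransportParams(flow_rate=80 * UL_MIN)
        hist = T.solve_transport(small_flow, par, t_end=4e5)
        assert T.diffusion_time(hist, 0.5) <= T.diffusion_time(hist, 0.9)

    def test_unreached_threshold_reports_attained_level(self, small_flow):
        par = T.TransportParams(flow_rate=80 * UL_MIN)
        hist = T.solve_transport(small_flow, par, t_end=200.0)
        with pytest.raises(ValueError, match="c0"):
            T.diffusion_time(hist, 0.99)

    def test_doubling_diffusivity_halves_time(self, small_device):
        """Pure-diffusion scaling: t(2D)/t(D) = 1/2 (t* invariance)."""
        dom = T.rasterize_device(small_device, dx=DX)
        fl = T.solve_flow(dom, 0.0)
        times = {}
        for D in (45.8e-12, 91.6e-12):
            par = T.TransportParams(diffusivity=D, flow_rate=0.0)
            hist = T.solve_transport(fl, par, t_end=6e5, hold_media=True, dt0=0.5)
            times[D] = T.diffusion_time(hist, 0.8)
        assert times[91.6e-12] / times[45.8e-12] == pytest.approx(0.5, rel=0.03)


class TestSlabOracle:
    def test_matches_fourier_series_solution(self):
        """Barrier fully open, no flow: centre trace follows the 1D slab series.

        The slab spans chamber + both barrier strips between media channels
        clamped at c0; the oracle is the classical Fourier-series solution
        averaged over the same centre window.
        """
        spec = G.PillarArraySpec(
            pore_size=8e-6,
            pillar_diameter=1e-6,
            n_pillars=0,
            pillar_height=150e-6,  # barrier as tall as the chamber: fully open
            strip_length=300e-6,
            strip_depth=125e-6,
        )
        dev = G.DeviceGeometry(300e-6, 150e-6, 300e-6, 100e-6, 150e-6, spec)
        dom = T.rasterize_device(dev, dx=DX)
        fl = T.solve_flow(dom, 0.0)
        par = T.TransportParams(flow_rate=0.0)
        hist = T.solve_transport(fl, par, t_end=2.5e3, hold_media=True, dt0=0.25)

        # analytic series for a slab of half-width a with walls at c0,
        # averaged over the centre window |x| <= s/2
        D, c0 = par.diffusivity, par.inlet_concentration
        a = (2 * 125e-6 + 300e-6) / 2.0
        s = 50e-6 / 2.0
        t = hist.times[1:]
        total = np.zeros_like(t)
        for n in range(0, 400):
            k = (2 * n + 1) * np.pi / (2 * a)
            coef = 4.0 / ((2 * n + 1) * np.pi) * (-1) ** n
            avg_cos = np.sin(k * s) / (k * s)
            total += coef * avg_cos * np.exp(-D * k**2 * t)
        expected = c0 * (1.0 - total)
        mask = expected > 0.05 * c0  # compare once the signal is resolvable
        err = np.abs(hist.cbar[1:][mask] - expected[mask]) / c0
        assert err.max() < 0.02


class TestTunability:
    def test_pore_size_sweep_non_increasing(self, small_device):
        par = T.TransportParams(flow_rate=20 * UL_MIN)
        tab = T.tunability_sweep(
            small_device, par, pore_sizes=[8e-6, 16e-6, 32e-6], dx=4e-6, t_end=4e5
        )
        times = tab["diffusion_time_s"].to_numpy()
        assert np.all(np.diff(times) <= 0)

    def test_sweep_argument_validation(self, small_device):
        par = T.TransportParams()
        with pytest.raises(ValueError):
            T.tunability_sweep(small_device, par)
        with pytest.raises(ValueError):
            T.tunability_sweep(small_device, par, heights=[2e-6], pore_sizes=[8e-6])

    def test_failed_configuration_is_annotated(self, small_device):
        par = T.TransportParams(flow_rate=20 * UL_MIN)
        with pytest.raises(RuntimeError, match="pore"):
            # pore so large the layout is infeasible
            T.tunability_sweep(small_device, par, pore_sizes=[200e-6], t_end=1e3)


class TestFickianDeviation:
    def test_zero_when_advection_globally_off(self, small_domain):
        fl = T.solve_flow(small_domain, 0.0)
        par = T.TransportParams(flow_rate=0.0)
        h1 = T.solve_transport(fl, par, t_end=2e4)
        h2 = T.solve_transport(fl, par, t_end=2e4, zero_advection_in_chamber=True)
        assert T.fickian_deviation(h1, h2) == pytest.approx(0.0, abs=1e-12)

    def test_non_decreasing_in_flow_rate(self, small_domain):
        devs = []
        for q in (5 * UL_MIN, 80 * UL_MIN):
            fl = T.solve_flow(small_domain, q)
            par = T.TransportParams(flow_rate=q)
            adv = T.solve_transport(fl, par, t_end=1.5e5)
            ref = T.solve_transport(fl, par, t_end=1.5e5, zero_advection_in_chamber=True)
            devs.append(T.fickian_deviation(adv, ref))
        assert devs[0] <= devs[1]

    def test_grid_mismatch_rejected(self, small_device, small_domain):
        fl1 = T.solve_flow(small_domain, 0.0)
        par = T.TransportParams(flow_rate=0.0)
        h1 = T.solve_transport(fl1, par, t_end=1e3)
        dom2 = T.rasterize_device(small_device, dx=10e-6)
        h2 = T.solve_transport(T.solve_flow(dom2, 0.0), par, t_end=1e3)
        with pytest.raises(ValueError, match="grid"):
            T.fickian_deviation(h1, h2)
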