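"""Scaling collapse: binning, rescaling, contiguity residual, exponent fits."""

import math

import numpy as np
import pandas as pd
import pytest

from mpsbarrier import scaling as S


def _lognormal_group(rng, n=1000):
    return rng.lognormal(0.0, 0.4, n)


class TestEmpiricalPdf:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        pdf = S.empirical_pdf(_lognormal_group(rng), 30)
        widths = np.diff(pdf.edges)
        occupied = np.isin(np.sqrt(pdf.edges[:-1] * pdf.edges[1:]), pdf.centers)
        assert np.sum(pdf.density * widths[occupied]) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_counting_oracle(self):
        rng = np.random.default_rng(1)
        samples = _lognormal_group(rng)
        pdf = S.empirical_pdf(samples, 25)
        counts = np.array(
            [
                np.sum((samples >= lo) & (samples < hi))
                for lo, hi in zip(pdf.edges[:-1], pdf.edges[1:])
            ]
        )
        counts[-1] += np.sum(samples == pdf.edges[-1])
        widths = np.diff(pdf.edges)
        oracle = (counts / (samples.size * widths))[counts > 0]
        np.testing.assert_allclose(pdf.density, oracle, rtol=1e-9)

    def test_all_equal_samples_single_bin(self):
        pdf = S.empirical_pdf(np.full(100, 3.0), 30)
        assert pdf.centers.size == 1
        widths = np.diff(pdf.edges)
        assert pdf.density[0] * widths[0] == pytest.approx(1.0, rel=1e-9)

    def test_rejects_nonpositive_and_small_samples(self):
        with pytest.raises(ValueError):
            S.empirical_pdf(np.array([-1.0] * 100))
        with pytest.raises(ValueError):
            S.empirical_pdf(np.ones(10))


class TestRescaleCurve:
    def test_identity_transform(self):
        pdf = S.empirical_pdf(_lognormal_group(np.random.default_rng(2)), 20)
        lx, ly = S.rescale_curve(pdf, m=5.0, alpha=0.0, gamma=0.0, beta=0.0)
        np.testing.assert_allclose(lx, np.log(pdf.centers))
        np.testing.assert_allclose(ly, np.log(pdf.density))

    def test_matches_pointwise_recomputation(self):
        pdf = S.empirical_pdf(_lognormal_group(np.random.default_rng(3)), 20)
        m, alpha, gamma, beta = 7.0, 0.9, 0.1, 1.0
        lx, ly = S.rescale_curve(pdf, m, alpha, gamma, beta)
        for k in range(pdf.centers.size):
            x = pdf.centers[k] / m**alpha
            y = pdf.density[k] * pdf.centers[k] ** beta * m**gamma
            assert lx[k] == pytest.approx(math.log(x), rel=1e-12)
            assert ly[k] == pytest.approx(math.log(y), rel=1e-12)

    def test_exact_power_law_family_collapses(self):
        """p(B) = B⁻¹ F(B/m^α₀) curves coincide after rescaling."""
        rng = np.random.default_rng(4)
        alpha0 = 0.9
        z = rng.lognormal(0.0, 0.3, 4000)
        curves = []
        for m in (1.0, 4.0, 16.0):
            pdf = S.empirical_pdf(m**alpha0 * z, 40)
            curves.append(S.rescale_curve(pdf, m, alpha0, 0.0, 1.0))
        r = S.collapse_residual(curves, q=1.0)
        assert r < 0.12  # binning noise only


class TestCollapseResidual:
    def test_identical_curves_zero(self):
        x = np.linspace(0, 1, 30)
        y = np.sin(x)
        assert S.collapse_residual([(x, y), (x, y)], 1.0) == 0.0

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(5)
        c1 = (np.sort(rng.uniform(0, 1, 25)), rng.normal(0, 1, 25))
        c2 = (np.sort(rng.uniform(0, 1, 25)), rng.normal(0, 1, 25))
        assert S.collapse_residual([c1, c2]) == S.collapse_residual([c2, c1])

    def test_flat_offset_curves_residual_equals_offset(self):
        x = np.linspace(0, 1, 20)
        delta = 0.37
        r = S.collapse_residual([(x, np.zeros(20)), (x, np.full(20, delta))], q=1.0)
        assert r == pytest.approx(delta, rel=1e-12)

    def test_disjoint_supports_give_sentinel(self):
        c1 = (np.linspace(0, 1, 20), np.zeros(20))
        c2 = (np.linspace(10, 11, 20), np.zeros(20))
        assert math.isinf(S.collapse_residual([c1, c2]))

    def test_fewer_than_two_curves(self):
        with pytest.raises(ValueError):
            S.collapse_residual([(np.arange(3.0), np.arange(3.0))])


def _constructed_dist(rng, alpha=0.9, masses=(1.0, 2.0, 4.0), n=1000):
    groups = []
    for m in masses:
        z = rng.lognormal(0.0, 0.5, n)
        groups.append((m, m**alpha * z, f"m={m}"))
    return S.DistributionSet.from_groups(groups)


class TestFitCollapse:
    def test_identical_distributions_give_zero_exponent(self):
        rng = np.random.default_rng(6)
        z = rng.lognormal(0.0, 0.5, 2000)
        dist = S.DistributionSet.from_groups([(m, z, f"m={m}") for m in (1.0, 3.0, 9.0)])
        res = S.fit_collapse(dist, S.CollapseParams(max_iter=150))
        assert res.alpha == pytest.approx(0.0, abs=0.02)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        dist = _constructed_dist(rng)
        p = S.CollapseParams(max_iter=80)
        r1 = S.fit_collapse(dist, p)
        r2 = S.fit_collapse(dist, p)
        assert (r1.alpha, r1.gamma, r1.residual) == (r2.alpha, r2.gamma, r2.residual)
        assert r1.master_curve.equals(r2.master_curve)

    def test_scale_invariance_of_alpha(self):
        rng = np.random.default_rng(8)
        dist = _constructed_dist(rng)
        scaled = S.DistributionSet.from_groups(
            [(m, 7.3 * b, lab) for m, b, lab in zip(dist.masses, dist.samples, dist.labels)]
        )
        p = S.CollapseParams(max_iter=150)
        assert S.fit_collapse(scaled, p).alpha == pytest.approx(
            S.fit_collapse(dist, p).alpha, abs=1e-6
        )

    def test_fitted_residual_beats_isometric_for_allometric_data(self):
        rng = np.random.default_rng(9)
        dist = _constructed_dist(rng, alpha=0.8)
        res = S.fit_collapse(dist, S.CollapseParams(max_iter=150))
        pdfs = [S.empirical_pdf(s, 30) for s in dist.samples]
        iso = S.collapse_residual(
            [S.rescale_curve(p, m, 1.0, 0.0, 1.0) for p, m in zip(pdfs, dist.masses)]
        )
        assert res.residual <= iso

    def test_distribution_set_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            S.DistributionSet.from_groups([(1.0, np.ones(100), "a")])
        with pytest.raises(ValueError, match="at least 50"):
            S.DistributionSet.from_groups([(1.0, np.ones(10), "a"), (2.0, np.ones(100), "b")])
        with pytest.raises(ValueError, match="distinct"):
            S.DistributionSet.from_groups(
                [(1.0, np.ones(100), "a"), (1.0, np.ones(100), "b")]
            )

    def test_from_frame_roundtrip(self):
        rng = np.random.default_rng(10)
        frame = pd.DataFrame(
            {
                "group": ["a"] * 100 + ["b"] * 100,
                "mass": [1.0] * 100 + [2.0] * 100,
                "B": np.concatenate([rng.lognormal(0, 0.3, 100), rng.lognormal(0.5, 0.3, 100)]),
            }
        )
        dist = S.DistributionSet.from_frame(frame)
        assert list(dist.labels) == ["a", "b"]
        assert dist.samples[0].size == 100
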