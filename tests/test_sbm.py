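"""Cluster profiles, the binding-profile estimator, and protein counts."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from parbsbm import sbm
from parbsbm.ensemble import DistanceSamples
from parbsbm.synthetic import AnalyticEnsembleSpec, generate_standin_samples

KINDS = sbm.CLUSTER_KINDS


class TestC0Profile:
    @pytest.mark.parametrize("kind", KINDS)
    def test_saturation_and_fwhm(self, kind):
        cm = sbm.ClusterModel(kind=kind, omega=50.0)
        assert sbm.c0_profile(cm, 0.0) == 1.0
        assert sbm.c0_profile(cm, 25.0) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("kind", KINDS)
    def test_monotone_non_increasing(self, kind):
        cm = sbm.ClusterModel(kind=kind, omega=40.0)
        r = np.linspace(0, 300, 1000)
        c = sbm.c0_profile(cm, r)
        assert np.all(np.diff(c) <= 1e-12)
        assert np.all((c >= 0) & (c <= 1))

    def test_leaky_values(self):
        cm = sbm.ClusterModel(kind="leaky", omega=40.0)
        # core saturation, then the 1/r halo: 1/2, 1/4, 1/8 at 20/40/80 nm
        assert sbm.c0_profile(cm, 5.0) == 1.0
        assert sbm.c0_profile(cm, 20.0) == pytest.approx(0.5)
        assert sbm.c0_profile(cm, 40.0) == pytest.approx(0.25)
        assert sbm.c0_profile(cm, 80.0) == pytest.approx(1.0 / 8.0)

    def test_tail_heaviness_ordering(self):
        # beyond the FWHM the tails order leaky ≥ exponential ≥ gaussian ≥ quenched
        r = np.linspace(41.0, 400.0, 200)
        tails = [sbm.c0_profile(sbm.ClusterModel(kind=k, omega=40.0), r)
                 for k in ("leaky", "exponential", "gaussian", "quenched")]
        for heavy, light in zip(tails, tails[1:]):
            assert np.all(heavy >= light - 1e-12)

    def test_negative_r_rejected(self):
        cm = sbm.ClusterModel(kind="leaky", omega=40.0)
        with pytest.raises(ValueError):
            sbm.c0_profile(cm, -1.0)

    def test_default_core_radii(self):
        assert sbm.ClusterModel(kind="leaky", omega=40.0).rho == 10.0
        assert sbm.ClusterModel(kind="quenched", omega=40.0).rho == 20.0


class TestCenterOffsetKernel:
    @pytest.mark.parametrize("r,rho", [(0.0, 10.0), (3.0, 10.0), (10.0, 10.0),
                                       (25.0, 10.0), (5.0, 40.0), (80.0, 15.0)])
    def test_normalization(self, r, rho):
        val, _ = quad(lambda x: sbm.center_offset_kernel(r, x, rho),
                      max(0.0, r - rho), r + rho, points=[abs(rho - r)],
                      epsabs=1e-12, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_uniform_ball_monte_carlo(self, rng):
        # Π_r(x) is the density of |probe − center| with the center uniform
        # in the ball of radius ρ around the centromere
        rho, r = 12.0, 8.0
        pts = rng.normal(size=(200_000, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= rho * rng.random(200_000)[:, None] ** (1 / 3)
        d = np.linalg.norm(pts - np.array([r, 0.0, 0.0]), axis=1)
        hist, edges = np.histogram(d, bins=50, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        expected = sbm.center_offset_kernel(r, centers, rho)
        assert np.max(np.abs(hist - expected)) < 0.005

    def test_zero_outside_support(self):
        assert sbm.center_offset_kernel(30.0, 5.0, 10.0) == 0.0
        assert sbm.center_offset_kernel(30.0, 45.0, 10.0) == 0.0

    def test_full_sphere_regime_at_origin(self):
        x = np.linspace(0, 10, 50)
        np.testing.assert_allclose(sbm.center_offset_kernel(0.0, x, 10.0),
                                   3 * x ** 2 / 1000.0)


class TestEffectiveConcentration:
    def test_no_convolution_returns_c0(self):
        cm = sbm.ClusterModel(kind="gaussian", omega=40.0)
        assert cm.convolve_center is False
        r = np.linspace(0, 100, 11)
        np.testing.assert_allclose(sbm.effective_concentration(cm, r),
                                   sbm.c0_profile(cm, r))

    def test_quenched_center_always_covers_origin(self):
        cm = sbm.ClusterModel(kind="quenched", omega=40.0)
        assert cm.convolve_center is True
        assert sbm.effective_concentration(cm, 0.0) == pytest.approx(1.0,
                                                                     abs=1e-9)

    def test_small_rho_limit_recovers_c0(self):
        cm = sbm.ClusterModel(kind="exponential", omega=40.0, rho=1e-3,
                              convolve_center=True)
        for r in (5.0, 20.0, 60.0):
            assert sbm.effective_concentration(cm, r) == \
                pytest.approx(sbm.c0_profile(cm, r), rel=1e-5)

    @pytest.mark.parametrize("kind", KINDS)
    def test_bounded_probabilities(self, kind):
        cm = sbm.ClusterModel(kind=kind, omega=40.0, convolve_center=True)
        c = sbm.effective_concentration(cm, np.linspace(0, 200, 40))
        assert np.all((c >= 0) & (c <= 1))


class TestBindingProfile:
    def test_zero_offset_is_saturated(self):
        ds = generate_standin_samples(AnalyticEnsembleSpec(),
                                      [0, 300, 3000], 500, seed=1)
        prof = sbm.binding_profile(ds, sbm.ClusterModel(kind="leaky",
                                                        omega=44.0))
        assert prof.values[0] == pytest.approx(1.0)
        assert np.all(np.isfinite(prof.values))

    def test_uniform_concentration_gives_unity(self):
        # a flat C ≡ 1 (huge saturated core) makes B(s) = 1 everywhere
        ds = generate_standin_samples(AnalyticEnsembleSpec(),
                                      [300, 1500, 9000], 500, seed=2)
        cm = sbm.ClusterModel(kind="quenched", omega=1e9,
                              convolve_center=False)
        prof = sbm.binding_profile(ds, cm)
        np.testing.assert_allclose(prof.values, 1.0)

    def test_sample_mean_matches_binned_integral(self):
        """The two estimators of ∫4πr²P_s(r)C(r)dr agree within MC error."""
        ds = generate_standin_samples(AnalyticEnsembleSpec(),
                                      [1500, 3000, 6000], 40_000, seed=3)
        cm = sbm.ClusterModel(kind="leaky", omega=44.0)
        prof = sbm.binding_profile(ds, cm)
        for s, b in zip(prof.s, prof.values):
            r = ds[int(s)]
            hist, edges = np.histogram(r, bins=200, density=True)
            centers = 0.5 * (edges[1:] + edges[:-1])
            c = np.asarray(sbm.effective_concentration(cm, centers))
            binned = float(np.sum(hist * c * np.diff(edges)))
            assert binned == pytest.approx(b, rel=0.01)

    def test_values_validated(self):
        with pytest.raises(ValueError, match="values"):
            sbm.BindingProfile(s=np.array([0.0, 30.0]),
                               values=np.array([0.5, 1.7]))


class TestProteinCount:
    def test_closed_form_matches_quadrature_oracle(self):
        cm = sbm.ClusterModel(kind="leaky", omega=36.0)
        for a in (5.0, 10.0, 15.0, 20.0):
            pp = sbm.ProteinCountParams(cell_radius=400.0, protein_radius=a)
            closed = sbm.protein_count(cm, pp)
            oracle, _ = quad(lambda r: sbm.c0_profile(cm, r) * 4 * np.pi * r ** 2,
                             0.0, 400.0, points=[9.0], epsabs=1e-12)
            oracle /= pp.protein_volume
            assert closed == pytest.approx(oracle, rel=1e-10)

    def test_inverse_cube_scaling_in_protein_size(self):
        cm = sbm.ClusterModel(kind="leaky", omega=36.0)
        n5 = sbm.protein_count(cm, sbm.ProteinCountParams(400.0, 5.0))
        n10 = sbm.protein_count(cm, sbm.ProteinCountParams(400.0, 10.0))
        assert n5 == pytest.approx(8.0 * n10, rel=1e-12)

    def test_non_leaky_rejected(self):
        cm = sbm.ClusterModel(kind="quenched", omega=36.0)
        with pytest.raises(ValueError, match="leaky"):
            sbm.protein_count(cm, sbm.ProteinCountParams(400.0, 5.0))


class TestScreeningLength:
    def test_reference_value(self):
        assert sbm.screening_length(1.0, 1.0) == pytest.approx(1000.0)

    def test_square_root_scaling(self):
        assert sbm.screening_length(1.0, 4.0) == \
            pytest.approx(sbm.screening_length(1.0, 1.0) / 2.0)

    def test_yukawa_solves_stationary_diffusion_dilution(self):
        """ρ e^{−r/ξ}/r must satisfy D r⁻² d/dr(r² dC/dr) = Γ C for r > ρ."""
        d_um, gamma = 1.0, 1.0
        xi = sbm.screening_length(d_um, gamma)      # nm
        d_nm = d_um * 1e6                            # nm²/s
        rho = 10.0

        def c(r):
            return rho * math.exp(-r / xi) / r

        # the spherical radial operator r⁻²d/dr(r²dC/dr) equals d²(rC)/dr²/r
        # identically; the latter form is numerically well conditioned
        h = 1e-2
        for r in (15.0, 50.0, 200.0, 800.0):
            x = lambda rr: rr * c(rr)
            lap = (x(r + h) - 2 * x(r) + x(r - h)) / (h ** 2 * r)
            assert d_nm * lap == pytest.approx(gamma * c(r), rel=1e-4)

    def test_leaky_params_container(self):
        lp = sbm.LeakyClusterParams(diffusion=1.0, dilution_rate=1.0,
                                    core_radius=9.0)
        assert lp.xi == pytest.approx(1000.0)
        assert lp.amplitude == 9.0
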