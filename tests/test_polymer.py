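"""Geometry, topology and energetics of the rod-like chain."""

import math

import numpy as np
import pytest

import parbsbm as pb
from parbsbm.polymer import (CYLINDER_LENGTH_NM, kappa_from_persistence,
                             mirror, persistence_length_estimate,
                             sample_joint_angles)

from conftest import scrambled_chain, writhe_brute_force


class TestBuildInitialCircle:
    def test_reference_plasmid_dimensions(self):
        conf = pb.build_initial_circle(30000, 0.0)
        assert conf.n_cylinders == 1000
        assert conf.relaxed_linking_number == 2850
        assert conf.linking_number == 2850
        assert conf.sigma == 0.0

    def test_supercoiled_linking_number(self):
        conf = pb.build_initial_circle(30000, -0.05)
        assert conf.linking_number == pytest.approx(2850 * 0.95)
        assert conf.sigma == pytest.approx(-0.05)

    def test_circle_radius_matches_circumference(self):
        conf = pb.build_initial_circle(3000, 0.0)
        # polygon circumradius is adjusted so sides are exactly l; for
        # N = 100 it is within a fraction of a percent of N·l/2π
        r = np.linalg.norm(conf.vertices, axis=1)
        assert np.allclose(r, r[0])
        assert r[0] == pytest.approx(100 * 10.2 / (2 * np.pi), rel=2e-4)

    def test_equilateral_and_closed(self):
        conf = pb.build_initial_circle(3000, 0.0)
        assert np.allclose(conf.segment_lengths(), CYLINDER_LENGTH_NM,
                           rtol=1e-9)
        conf.validate(pb.EnergyModel())

    def test_planar_circle_has_zero_writhe(self, circle_3kb):
        assert pb.writhe(circle_3kb) == pytest.approx(0.0, abs=1e-8)

    def test_non_divisible_bp_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            pb.build_initial_circle(1234, 0.0)

    def test_untested_sigma_warns(self):
        with pytest.warns(UserWarning, match="untested"):
            pb.build_initial_circle(3000, -0.2)


class TestEnergyModel:
    def test_positive_lengths_enforced(self):
        with pytest.raises(ValueError):
            pb.EnergyModel(persistence_length=-1.0)

    def test_discrete_wlc_kappa_reproduces_tangent_decorrelation(self):
        em = pb.EnergyModel()
        k = em.kappa
        # <cos θ> = coth κ − 1/κ must equal exp(−l/l_p)
        assert 1 / math.tanh(k) - 1 / k == pytest.approx(
            math.exp(-10.2 / 50.0), abs=1e-12)

    def test_ratio_mapping(self):
        assert kappa_from_persistence(50.0, 10.2, "ratio") == \
            pytest.approx(4.902, abs=1e-3)


class TestBendingEnergy:
    def test_regular_polygon_closed_form(self, energy_model):
        for n_bp in (3000, 9000):
            conf = pb.build_initial_circle(n_bp, 0.0)
            n = conf.n_cylinders
            expected = energy_model.kappa * n * (1 - np.cos(2 * np.pi / n))
            assert pb.bending_energy(conf, energy_model) == \
                pytest.approx(expected, rel=1e-10)

    def test_single_right_angle_joint(self):
        # open-chain style check embedded in a closed polygon: compare two
        # circles differing by a known joint perturbation is awkward, so use
        # the ratio mapping directly on the formula κ(1 − cos θ)
        em = pb.EnergyModel(bending_mapping="ratio")
        assert em.kappa * (1 - math.cos(math.pi / 2)) == \
            pytest.approx(4.902, abs=1e-3)


class TestTorsionalEnergy:
    def test_relaxed_chain_zero(self, circle_3kb, energy_model):
        assert pb.torsional_energy(circle_3kb, energy_model) == \
            pytest.approx(0.0, abs=1e-12)

    def test_all_supercoiling_in_writhe_gives_zero(self, energy_model):
        conf = pb.build_initial_circle(3000, 0.0)
        conf.linking_number -= 2.0
        assert pb.torsional_energy(conf, energy_model, wr=-2.0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_uniform_twist_formula(self, energy_model):
        conf = pb.build_initial_circle(30000, 0.0)
        conf.linking_number -= 10.0
        e = pb.torsional_energy(conf, energy_model, wr=0.0)
        assert e == pytest.approx(2 * np.pi ** 2 * 86 * 100 / 10200, rel=1e-12)


class TestWrithe:
    def test_closed_form_vs_gauss_integral_oracle(self):
        """Segment-pair closed form vs brute-force double integral, N ≤ 40."""
        for trial in range(10):
            conf = scrambled_chain(12 + 3 * trial, seed=100 + trial)
            w_closed = pb.writhe(conf)
            w_brute = writhe_brute_force(conf.vertices, q=40)
            assert abs(w_closed - w_brute) <= 1e-3

    def test_figure_eight_single_crossing(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        curve = np.column_stack([np.sin(t), np.sin(t) * np.cos(t),
                                 0.02 * np.cos(t)])
        assert abs(abs(pb.writhe(curve)) - 1.0) <= 0.05
        assert abs(pb.writhe(curve) - writhe_brute_force(curve, q=8)) <= 1e-3

    def test_mirror_antisymmetry(self):
        for trial in range(5):
            conf = scrambled_chain(15 + trial, seed=40 + trial)
            assert pb.writhe(mirror(conf)) == pytest.approx(-pb.writhe(conf),
                                                            abs=1e-10)

    def test_coincident_vertices_rejected(self):
        v = np.zeros((10, 3))
        with pytest.raises(ValueError, match="coincident"):
            pb.writhe(v)


class TestSelfAvoidance:
    def test_planar_circle_clear(self, circle_3kb):
        assert pb.check_self_avoidance(circle_3kb)
        assert pb.check_self_avoidance(circle_3kb, moved_range=(10, 30))

    @pytest.mark.parametrize("gap,ok", [(3.9, False), (4.1, True)])
    def test_parallel_segment_hard_core(self, gap, ok):
        # two parallel two-cylinder rails stacked at separation `gap`,
        # connected by short end rungs into a closed loop
        l = CYLINDER_LENGTH_NM
        v = np.array([
            [0.0, 0.0, 0.0], [l, 0.0, 0.0], [2 * l, 0.0, 0.0],
            [2 * l, 0.0, gap], [l, 0.0, gap], [0.0, 0.0, gap],
        ])
        conf = pb.ChainConformation(vertices=v, linking_number=0,
                                    relaxed_linking_number=1)
        assert pb.check_self_avoidance(conf) is ok


class TestRadiusOfGyration:
    def test_circle_radius(self, circle_3kb):
        r = np.linalg.norm(circle_3kb.vertices[0])
        assert pb.radius_of_gyration(circle_3kb) == pytest.approx(r, rel=1e-12)

    def test_antipodal_clusters(self):
        pts = np.array([[5.0, 0, 0]] * 7 + [[-5.0, 0, 0]] * 7)
        assert pb.radius_of_gyration(pts) == pytest.approx(5.0)


class TestTopologyBookkeeping:
    def test_identity_lk_decomposition(self):
        conf = scrambled_chain(20, seed=9)
        conf.linking_number -= 3.0
        ts = pb.TopologyState.from_conformation(conf)
        d_lk = conf.linking_number - conf.relaxed_linking_number
        assert ts.twist_deficit + ts.writhe == pytest.approx(d_lk, abs=1e-12)


class TestPersistenceCalibration:
    def test_tangent_correlation_recovers_lp(self, rng):
        """−l/ln⟨cos θ⟩ from 2×10⁵ equilibrium joints recovers l_p within 5%."""
        em = pb.EnergyModel()
        angles = sample_joint_angles(em, 200_000, rng)
        lp = persistence_length_estimate(angles)
        assert lp == pytest.approx(50.0, rel=0.05)

    def test_ratio_mapping_underestimates_lp(self, rng):
        # the naive κ = l_p/l mapping yields a discernibly shorter
        # persistence length at this coarse discretization
        em = pb.EnergyModel(bending_mapping="ratio")
        angles = sample_joint_angles(em, 200_000, rng)
        assert persistence_length_estimate(angles) < 48.0
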