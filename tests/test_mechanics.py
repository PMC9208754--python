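"""Closed-form buckling-delamination mechanics and channel hydrodynamics."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from wrinklekit import mechanics as m

FILM = m.ElasticFilm(youngs_modulus=1000.0, poisson_ratio=0.45, thickness=15e-6)


class TestCriticalStress:
    def test_reference_biofilm_parameters(self):
        # E_f = 1000 Pa, nu = 0.45, h = 15 um blister R = 10 um: the critical
        # stress is ~3.45 kPa, i.e. ~3500 Pa at the customary rounding
        sigma_c = m.critical_stress(FILM, m.Blister(10e-6))
        assert sigma_c == pytest.approx(3451.88, rel=1e-4)
        assert sigma_c == pytest.approx(3500, rel=0.02)

    def test_unit_inputs_reduce_to_coefficient(self):
        film = m.ElasticFilm(1.0, 0.0, 1.0)
        assert m.critical_stress(film, m.Blister(1.0)) == pytest.approx(1.2235)

    def test_halving_radius_quadruples_stress(self):
        s1 = m.critical_stress(FILM, m.Blister(10e-6))
        s2 = m.critical_stress(FILM, m.Blister(5e-6))
        assert s2 == pytest.approx(4.0 * s1)

    def test_single_cell_blister_is_100x(self):
        # shrinking the blister from 10 um to 1 um (single-cell scale) raises
        # the buckling stress by exactly two orders of magnitude
        s10 = m.critical_stress(FILM, m.Blister(10e-6))
        s1 = m.critical_stress(FILM, m.Blister(1e-6))
        assert s1 / s10 == pytest.approx(100.0, rel=1e-12)

    @given(
        e=st.floats(1.0, 1e6),
        nu=st.floats(0.0, 0.49),
        scale=st.floats(0.1, 10.0),
    )
    def test_homogeneity(self, e, nu, scale):
        """Degree 1 in E_f; degree 2 in the h/R aspect ratio."""
        film = m.ElasticFilm(e, nu, 10e-6)
        base = m.critical_stress(film, m.Blister(20e-6))
        scaled_e = m.ElasticFilm(scale * e, nu, 10e-6)
        assert m.critical_stress(scaled_e, m.Blister(20e-6)) == pytest.approx(scale * base, rel=1e-9)
        scaled_h = m.ElasticFilm(e, nu, scale * 10e-6)
        assert m.critical_stress(scaled_h, m.Blister(20e-6)) == pytest.approx(
            scale**2 * base, rel=1e-9
        )

    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(youngs_modulus=-1.0, poisson_ratio=0.4, thickness=1e-6), "youngs_modulus"),
            (dict(youngs_modulus=1.0, poisson_ratio=0.5, thickness=1e-6), "poisson_ratio"),
            (dict(youngs_modulus=1.0, poisson_ratio=0.4, thickness=0.0), "thickness"),
        ],
    )
    def test_validation_names_offending_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            m.ElasticFilm(**kwargs)
        with pytest.raises(ValueError, match="radius"):
            m.Blister(-1e-6)


class TestEnergyRelease:
    def test_zero_stress_stores_no_energy(self):
        assert m.baseline_energy_release(FILM, m.StressState(0.0)) == 0.0

    def test_reference_value_hand_evaluated(self):
        g0 = m.baseline_energy_release(FILM, m.StressState(3500.0))
        assert g0 == pytest.approx(0.55 * 15e-6 * 3500**2 / 1000.0, rel=1e-12)

    def test_quadratic_in_stress(self):
        g1 = m.baseline_energy_release(FILM, m.StressState(1000.0))
        g2 = m.baseline_energy_release(FILM, m.StressState(2000.0))
        assert g2 == pytest.approx(4.0 * g1)

    def test_zero_at_critical_stress(self):
        out = m.normalized_energy_release(m.StressState(3500.0), 3500.0, 0.45)
        assert out.ratio == 0.0
        assert out.buckled

    def test_unbuckled_below_critical_is_flag_not_error(self):
        out = m.normalized_energy_release(m.StressState(1000.0), 3500.0, 0.45)
        assert out.ratio == 0.0
        assert not out.buckled

    def test_large_stress_asymptote(self):
        limit = 1.0 / (1.0 + 0.9021 * 0.55)
        out = m.normalized_energy_release(m.StressState(1e12), 3500.0, 0.45)
        assert out.ratio == pytest.approx(limit, abs=1e-9)

    def test_double_critical_stress(self):
        c2 = m.mode_mix_factor(0.45)
        out = m.normalized_energy_release(m.StressState(7000.0), 3500.0, 0.45)
        assert out.ratio == pytest.approx(c2 * 0.75, rel=1e-12)

    @given(ratio=st.floats(1.0, 100.0), nu=st.floats(0.0, 0.49))
    def test_bounded_and_monotone(self, ratio, nu):
        """G/G0 lies in [0, c2) and grows with stress."""
        c2 = m.mode_mix_factor(nu)
        out = m.normalized_energy_release(m.StressState(ratio * 100.0), 100.0, nu)
        assert 0.0 <= out.ratio < c2
        higher = m.normalized_energy_release(m.StressState((ratio + 0.5) * 100.0), 100.0, nu)
        assert higher.ratio > out.ratio or ratio == pytest.approx(1.0)


class TestVerdict:
    @pytest.mark.parametrize(
        "g,gamma,expected",
        [(1.0, 2.0, m.Verdict.ARRESTED), (2.0, 1.0, m.Verdict.GROWS), (1.0, 1.0, m.Verdict.ARRESTED)],
    )
    def test_crack_growth_criterion(self, g, gamma, expected):
        assert m.delamination_verdict(g, m.InterfaceToughness(gamma)) is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.delamination_verdict(-1.0, m.InterfaceToughness(1.0))
        with pytest.raises(ValueError, match="toughness"):
            m.InterfaceToughness(-1.0)


class TestMinBucklingRadius:
    def test_inverts_critical_stress(self):
        r = 13e-6
        sigma = m.critical_stress(FILM, m.Blister(r))
        assert m.min_buckling_radius(FILM, m.StressState(sigma)) == pytest.approx(r, rel=1e-12)

    def test_reference_inversion(self):
        r = m.min_buckling_radius(FILM, m.StressState(3500.0))
        assert r == pytest.approx(10e-6, rel=0.01)

    def test_sqrt_scaling(self):
        r1 = m.min_buckling_radius(FILM, m.StressState(100.0))
        r2 = m.min_buckling_radius(FILM, m.StressState(10000.0))
        assert r1 / r2 == pytest.approx(10.0)

    def test_zero_stress_never_buckles(self):
        assert m.min_buckling_radius(FILM, m.StressState(0.0)) == math.inf


class TestHydrodynamics:
    FLOW = m.ChannelFlow(
        width=500e-6,
        height=100e-6,
        flow_rate=m.ml_per_h_to_m3_per_s(0.3),
        viscosity=1e-3,
    )

    def test_mean_velocity_in_growth_channel(self):
        # 0.3 ml/h through a 500 x 100 um channel is ~1.7 mm/s
        assert m.mean_velocity(self.FLOW) == pytest.approx(1.7e-3, rel=0.03)

    def test_wall_shear_stress_in_growth_channel(self):
        assert m.wall_shear_stress(self.FLOW) == pytest.approx(0.1, rel=0.05)

    def test_zero_flow(self):
        still = m.ChannelFlow(500e-6, 100e-6, 0.0, 1e-3)
        assert m.mean_velocity(still) == 0.0
        assert m.wall_shear_stress(still) == 0.0

    def test_doubling_width_halves_velocity(self):
        wide = m.ChannelFlow(1000e-6, 100e-6, self.FLOW.flow_rate, 1e-3)
        assert m.mean_velocity(wide) == pytest.approx(0.5 * m.mean_velocity(self.FLOW))

    def test_shear_consistent_with_velocity_route(self):
        tau = m.wall_shear_stress(self.FLOW)
        u = m.mean_velocity(self.FLOW)
        assert tau == 6.0 * self.FLOW.viscosity * u / self.FLOW.height

    def test_printed_values_round_trip(self):
        """0.3 ml/h -> 1.7 mm/s -> 0.1 Pa within printed rounding."""
        u = m.mean_velocity(self.FLOW)
        assert round(u * 1e3, 1) == 1.7
        assert round(m.wall_shear_stress(self.FLOW), 1) == 0.1
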