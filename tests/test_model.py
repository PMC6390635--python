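"""Closed-form forward model: exact values, symmetry, conservation, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from issdiff import (
    ContinuousSource,
    DiffusionParameters,
    InstantaneousSource,
    InvalidInputError,
    SpacetimePoint,
    average_diffusion,
    concentration_continuous,
    concentration_instantaneous,
    half_life,
    tortuosity,
    total_dissolved_mass,
)
from conftest import quadrature_total_mass


class TestInstantaneous:
    def test_unit_value_at_origin(self):
        """With D=1, k=0, alpha=1 and t=1/pi, (pi t)^{3/2}=1 so C(0)=M/8."""
        p = DiffusionParameters(d_x=1, d_y=1, d_z=1, k=0, alpha=1)
        s = InstantaneousSource(mass=1.0)
        c = concentration_instantaneous(p, s, [SpacetimePoint(0, 0, 0, 1 / np.pi)])
        assert c[0] == pytest.approx(0.125, rel=1e-14)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        x=st.floats(-3, 3), y=st.floats(-3, 3), z=st.floats(-3, 3),
        t=st.floats(60, 21600),
        dx=st.floats(0.38e-4, 20e-4), dy=st.floats(0.38e-4, 20e-4),
        dz=st.floats(0.38e-4, 20e-4), k=st.floats(0, 1e-4),
    )
    def test_evenness_and_nonnegativity(self, x, y, z, t, dx, dy, dz, k):
        """C is even in each coordinate and never negative."""
        p = DiffusionParameters(d_x=dx, d_y=dy, d_z=dz, k=k, alpha=0.2)
        s = InstantaneousSource(mass=2.0)
        pts = np.array([[sx * x, sy * y, sz * z, t]
                        for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)])
        c = concentration_instantaneous(p, s, pts)
        assert np.all(c >= 0)
        assert np.allclose(c, c[0], rtol=1e-13)

    def test_linear_in_mass_inverse_in_alpha(self, aniso_params):
        pts = np.array([[0.5, -0.3, 0.2, 1800.0]])
        c1 = concentration_instantaneous(aniso_params, InstantaneousSource(mass=1.0), pts)
        c2 = concentration_instantaneous(aniso_params, InstantaneousSource(mass=2.0), pts)
        assert c2[0] == pytest.approx(2 * c1[0], rel=1e-14)
        p_half = DiffusionParameters(d_x=aniso_params.d_x, d_y=aniso_params.d_y,
                                     d_z=aniso_params.d_z, k=aniso_params.k,
                                     alpha=aniso_params.alpha / 2)
        c3 = concentration_instantaneous(p_half, InstantaneousSource(mass=1.0), pts)
        assert c3[0] == pytest.approx(2 * c1[0], rel=1e-14)

    def test_quadrature_matches_analytic_mass(self, aniso_params, unit_bolus):
        """Numerical quadrature over a +/-20 mm cube equals (M/alpha)e^{-kt}."""
        t = 3600.0
        num = quadrature_total_mass(aniso_params, unit_bolus, t)
        exact = total_dissolved_mass(aniso_params, unit_bolus, t)
        assert num == pytest.approx(exact, rel=1e-6)

    def test_isotropic_second_moment_is_2dt(self):
        """Isotropic k=0 heat kernel: per-axis variance of the normalised
        field equals 2 D t (quadrature check)."""
        d, t = 2.5e-4, 3600.0
        p = DiffusionParameters(d_x=d, d_y=d, d_z=d, k=0.0, alpha=1.0)
        # marginal along x is a 1-D Gaussian; second moment by quadrature
        var = 4 * d * t / 2
        num, _ = integrate.quad(
            lambda u: u * u * math.exp(-u * u / (4 * d * t))
            / math.sqrt(4 * math.pi * d * t),
            -20, 20, epsrel=1e-11, epsabs=0.0, points=[0.0])
        assert num == pytest.approx(2 * d * t, rel=1e-6)
        assert var == pytest.approx(2 * d * t, rel=1e-12)

    def test_invalid_inputs(self, aniso_params, unit_bolus):
        with pytest.raises(InvalidInputError):
            concentration_instantaneous(aniso_params, unit_bolus,
                                        [SpacetimePoint(0, 0, 0, 0.0)])
        with pytest.raises(InvalidInputError):
            concentration_instantaneous(aniso_params, unit_bolus,
                                        np.array([[np.nan, 0, 0, 10.0]]))


class TestContinuous:
    def test_zero_rate_gives_zero(self, aniso_params):
        s = ContinuousSource(c0=10.0, q=0.0, duration=600.0)
        c = concentration_continuous(aniso_params, s,
                                     np.array([[0.5, 0, 0, 1800.0]]))
        assert c[0] == 0.0

    def test_short_infusion_limits_to_bolus(self, aniso_params):
        """duration -> 0 at fixed total mass converges to the bolus solution."""
        t, mass = 3600.0, 20.0
        dur = t / 1e4
        s = ContinuousSource(c0=10.0, q=mass / (10.0 * dur), duration=dur)
        pts = np.array([[1.0, 0.5, -0.5, t]])
        cc = concentration_continuous(aniso_params, s, pts)[0]
        ci = concentration_instantaneous(aniso_params,
                                         InstantaneousSource(mass=mass), pts)[0]
        assert cc == pytest.approx(ci, rel=1e-3)

    def test_matches_riemann_superposition(self, aniso_params):
        """Quadrature equals a 1e4-term micro-bolus superposition (0.5%)."""
        s = ContinuousSource(c0=10.0, q=0.2 / 60.0, duration=600.0)  # 2 ul over 10 min
        t = 3600.0
        pts = np.array([[1.0, 0.5, -0.5, t]])
        cc = concentration_continuous(aniso_params, s, pts)[0]
        n = 10_000
        taus = (np.arange(n) + 0.5) * s.duration / n
        dm = s.c0 * s.q * s.duration / n
        elapsed = t - taus
        brute = np.sum(concentration_instantaneous(
            aniso_params, InstantaneousSource(mass=dm),
            np.column_stack([np.full(n, 1.0), np.full(n, 0.5),
                             np.full(n, -0.5), elapsed])))
        assert cc == pytest.approx(brute, rel=5e-3)

    def test_nonnegative(self, aniso_params):
        s = ContinuousSource(c0=10.0, q=0.2 / 60.0, duration=600.0)
        pts = np.array([[x, 0.0, 0.0, 900.0] for x in (0.1, 1.0, 3.0)])
        assert np.all(concentration_continuous(aniso_params, s, pts) >= 0)


class TestTotalDissolvedMass:
    def test_no_clearance_conserves(self, unit_bolus):
        p = DiffusionParameters(d_x=1e-4, d_y=1e-4, d_z=1e-4, k=0.0, alpha=0.25)
        for t in (60.0, 3600.0, 86400.0):
            assert total_dissolved_mass(p, unit_bolus, t) == pytest.approx(4.0, rel=1e-14)

    def test_value_and_quadrature(self, unit_bolus):
        p = DiffusionParameters(d_x=1e-4, d_y=1.5e-4, d_z=0.8e-4, k=1.4e-5, alpha=0.2)
        m = total_dissolved_mass(p, unit_bolus, 600.0)
        assert m == pytest.approx(5.0 * math.exp(-8.4e-3), rel=1e-12)
        assert quadrature_total_mass(p, unit_bolus, 600.0) == pytest.approx(m, rel=1e-6)

    def test_linear_in_mass_and_decreasing(self, aniso_params):
        m1 = total_dissolved_mass(aniso_params, InstantaneousSource(mass=1.0), 600.0)
        m2 = total_dissolved_mass(aniso_params, InstantaneousSource(mass=2.0), 600.0)
        assert m2 == pytest.approx(2 * m1, rel=1e-14)
        later = total_dissolved_mass(aniso_params, InstantaneousSource(mass=1.0), 1200.0)
        assert later < m1

    def test_requires_time_after_release(self, aniso_params, unit_bolus):
        with pytest.raises(InvalidInputError):
            total_dissolved_mass(aniso_params, unit_bolus, 0.0)


class TestDerivedMetrics:
    def test_average_diffusion_conventions(self):
        d = 1.3e-4
        iso = DiffusionParameters(d_x=d, d_y=d, d_z=d)
        assert average_diffusion(iso, "rss") == pytest.approx(d * math.sqrt(3), rel=1e-14)
        assert average_diffusion(iso, "rms") == pytest.approx(d, rel=1e-14)
        assert average_diffusion(iso, "mean") == pytest.approx(d, rel=1e-14)
        with pytest.raises(InvalidInputError):
            DiffusionParameters(d_x=3.0, d_y=4.0, d_z=0.0)
        p345 = DiffusionParameters(d_x=3.0, d_y=4.0, d_z=1e-12)
        assert average_diffusion(p345, "rss") == pytest.approx(5.0, rel=1e-9)
        with pytest.raises(InvalidInputError):
            average_diffusion(iso, "geometric")

    def test_half_life(self):
        assert half_life(math.log(2.0)) == pytest.approx(1.0, rel=1e-14)
        assert half_life(1.4e-5) == pytest.approx(4.951e4, rel=1e-3)
        assert half_life(0.5e-5) == pytest.approx(2 * half_life(1e-5), rel=1e-14)
        with pytest.raises(InvalidInputError):
            half_life(0.0)

    def test_tortuosity(self):
        assert tortuosity(1e-3, 1e-3) == pytest.approx(1.0)
        assert tortuosity(4e-4, 1e-4) == pytest.approx(2.0)
        lams = [tortuosity(1e-3, de) for de in (1e-4, 2e-4, 5e-4, 1e-3)]
        assert all(a > b for a, b in zip(lams, lams[1:]))
        with pytest.raises(InvalidInputError):
            tortuosity(-1.0, 1.0)
        with pytest.raises(InvalidInputError):
            tortuosity(1.0, 0.0)


class TestParameterValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(d_x=0.0, d_y=1e-4, d_z=1e-4),
        dict(d_x=1e-4, d_y=1e-4, d_z=1e-4, k=-1e-6),
        dict(d_x=1e-4, d_y=1e-4, d_z=1e-4, alpha=0.0),
        dict(d_x=1e-4, d_y=1e-4, d_z=1e-4, alpha=1.5),
    ])
    def test_rejects_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidInputError):
            DiffusionParameters(**kwargs)

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(InvalidInputError):
            InstantaneousSource(mass=0.0)
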