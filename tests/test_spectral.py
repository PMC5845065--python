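"""Analytic decay-rate machinery against published reference values and
algebraic identities."""

import math

import numpy as np
import pytest

import viscopulse as vp
from tests.conftest import FIG_GEOM, maxwell_c5, zener_c43


class TestGeometry:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            vp.TubeGeometry(r=-0.004, e=0.0005, L=1.0, rho=1000.0)

    def test_rejects_thick_wall(self):
        with pytest.raises(ValueError):
            vp.TubeGeometry(r=0.004, e=0.0025, L=1.0, rho=1000.0)

    def test_warns_in_marginal_thickness(self):
        with pytest.warns(UserWarning):
            vp.TubeGeometry(r=0.004, e=0.0017, L=1.0, rho=1000.0)


class TestWaveSpeeds:
    def test_reference_maxwell_speed_is_5(self):
        assert vp.wave_speed_maxwell(maxwell_c5(2.0), FIG_GEOM).c == \
            pytest.approx(5.0, rel=1e-12)

    def test_speed_scalings(self):
        m = maxwell_c5(2.0)
        thin = vp.TubeGeometry(r=FIG_GEOM.r, e=FIG_GEOM.e / 4,
                               L=FIG_GEOM.L, rho=FIG_GEOM.rho)
        assert vp.wave_speed_maxwell(m, thin).c == pytest.approx(2.5)
        dense = vp.TubeGeometry(r=FIG_GEOM.r, e=FIG_GEOM.e,
                                L=FIG_GEOM.L, rho=2 * FIG_GEOM.rho)
        assert vp.wave_speed_maxwell(m, dense).c == \
            pytest.approx(5.0 / math.sqrt(2.0))

    def test_zener_pythagorean_combination(self):
        s = vp.wave_speeds_zener(zener_c43(2.0), FIG_GEOM)
        assert (s.c0, s.c1) == (pytest.approx(4.0), pytest.approx(3.0))
        assert s.c == pytest.approx(5.0, rel=1e-12)

    def test_pdms_carotid_speed(self, pdms, carotid):
        """Fitted silicone card in a 4 mm / 0.5 mm conduit propagates
        pulses at 13.808 m/s."""
        assert vp.wave_speeds_zener(pdms, carotid).c == \
            pytest.approx(13.808, abs=5e-4)

    def test_zero_E0_reduces_to_maxwell(self):
        z = vp.ZenerMaterial(E0=1e-30, E1=9.0e5, tau=0.3)
        m = vp.MaxwellMaterial(E1=9.0e5, tau=0.3)
        assert vp.wave_speeds_zener(z, FIG_GEOM).c == \
            pytest.approx(vp.wave_speed_maxwell(m, FIG_GEOM).c, rel=1e-9)


class TestMaxwellSpectrum:
    def test_dominant_overdamped_rate(self):
        """tau=0.2 s, c=5 m/s, L=10 m: the slow overdamped n=1 rate is
        mu_11 = -0.555 1/s."""
        spec = vp.maxwell_spectrum(maxwell_c5(0.2), FIG_GEOM, n_max=5)
        mu11 = spec.modes[0].rates[0].real
        assert mu11 == pytest.approx(-0.555, abs=5e-4)
        assert spec.modes[0].regime == "overdamped"

    def test_all_underdamped_when_tau_large(self):
        spec = vp.maxwell_spectrum(maxwell_c5(2.0), FIG_GEOM, n_max=50)
        assert all(m.regime == "underdamped" for m in spec.modes)
        assert spec.k_critical == 0

    def test_undamped_wave_limit(self):
        """tau -> inf: rates become +/- i c sqrt(lambda_n)."""
        spec = vp.maxwell_spectrum(
            vp.MaxwellMaterial(E1=maxwell_c5(1.0).E1, tau=1e8),
            FIG_GEOM, n_max=3)
        for mode in spec.modes:
            expected = 5.0 * math.sqrt(mode.lambda_n)
            assert mode.omega_n == pytest.approx(expected, rel=1e-9)
            assert abs(mode.rates[0].real) < 1e-7

    def test_overdamped_ordering(self):
        """mu_2n < -1/(2 tau) < mu_1n < 0 for all overdamped modes."""
        m = maxwell_c5(0.05)
        spec = vp.maxwell_spectrum(m, FIG_GEOM, n_max=80)
        half = 1.0 / (2.0 * m.tau)
        over = [md for md in spec.modes if md.regime == "overdamped"]
        assert over and over[-1].n <= spec.k_critical
        for md in over:
            mu1, mu2 = md.rates[0].real, md.rates[1].real
            assert mu2 < -half < mu1 < 0

    def test_tau_eq_underdamped_branch(self):
        assert vp.maxwell_tau_eq(maxwell_c5(2.0), FIG_GEOM) == \
            pytest.approx(4.0, rel=1e-12)

    def test_tau_eq_equals_reciprocal_mu11_in_overdamped_branch(self):
        m = maxwell_c5(0.2)
        spec = vp.maxwell_spectrum(m, FIG_GEOM, n_max=1)
        mu11 = spec.modes[0].rates[0].real
        assert vp.maxwell_tau_eq(m, FIG_GEOM) == \
            pytest.approx(-1.0 / mu11, rel=1e-12)

    def test_tau_eq_continuous_at_branch_boundary(self):
        # tau such that 4 tau^2 pi^2 c^2 / L^2 = 1 exactly
        tau_star = FIG_GEOM.L / (2.0 * math.pi * 5.0)
        m = maxwell_c5(tau_star)
        assert vp.maxwell_tau_eq(m, FIG_GEOM) == \
            pytest.approx(2.0 * tau_star, rel=1e-9)


class TestZenerRoots:
    @pytest.mark.parametrize("tau,n,expected", [
        (2.0, 1, 11.59), (0.2, 1, 11.606), (0.2, 5, 1.332),
        (0.05, 1, 45.11), (0.05, 8, 0.820), (0.05, 10, 0.588),
    ])
    def test_published_decay_constants(self, tau, n, expected):
        """Modal decay times for c0=4, c1=3 m/s, L=10 m."""
        got = vp.zener_decay_constant(zener_c43(tau), FIG_GEOM, n)
        assert got == pytest.approx(expected, rel=1e-2)

    def test_vieta_identities(self):
        """Root sum, pairwise sum and product match the cubic's
        coefficients."""
        z = zener_c43(0.7)
        lam = FIG_GEOM.lambda_n(3)
        r1, r2, r3 = vp.zener_mode_roots(z, FIG_GEOM, 3)
        assert (r1 + r2 + r3).real == pytest.approx(1.0 / z.tau, rel=1e-9)
        assert abs((r1 + r2 + r3).imag) < 1e-9 / z.tau
        pair = r1 * r2 + r1 * r3 + r2 * r3
        assert pair.real == pytest.approx(lam * 25.0, rel=1e-9)
        prod = r1 * r2 * r3
        assert prod.real == pytest.approx(lam * 16.0 / z.tau, rel=1e-9)

    def test_cardano_vs_companion_matrix_on_random_draws(self):
        """Closed-form roots agree with a numerical cubic solve to 1e-9
        over a broad random parameter sweep (the function itself raises
        on disagreement)."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tau = 10.0 ** rng.uniform(-2, 1)
            c0 = 10.0 ** rng.uniform(-0.5, 1.5)
            c1 = 10.0 ** rng.uniform(-0.5, 1.5)
            L = 10.0 ** rng.uniform(-1, 1.5)
            n = int(rng.integers(1, 30))
            scale = FIG_GEOM.e / (2.0 * FIG_GEOM.rho * FIG_GEOM.r)
            z = vp.ZenerMaterial(E0=c0 ** 2 / scale, E1=c1 ** 2 / scale,
                                 tau=tau)
            geom = vp.TubeGeometry(r=FIG_GEOM.r, e=FIG_GEOM.e, L=L,
                                   rho=FIG_GEOM.rho)
            roots = vp.zener_mode_roots(z, geom, n)
            assert all(r.real >= -1e-9 for r in roots)

    def test_zero_E0_roots_match_maxwell_rates(self):
        """c0 = 0 collapses the cubic to x (x^2 - x/tau + lam c1^2):
        the nonzero roots are the negated Maxwell rates."""
        scale = FIG_GEOM.e / (2.0 * FIG_GEOM.rho * FIG_GEOM.r)
        z = vp.ZenerMaterial(E0=1e-25, E1=9.0 / scale, tau=0.2)
        m = vp.MaxwellMaterial(E1=9.0 / scale, tau=0.2)
        for n in (1, 4):
            roots = sorted(vp.zener_mode_roots(z, FIG_GEOM, n),
                           key=lambda r: abs(r))
            assert abs(roots[0]) < 1e-9
            mu = sorted((md.rates for md in
                         vp.maxwell_spectrum(m, FIG_GEOM, n).modes
                         if md.n == n))[0]
            expect = sorted([-mu[0], -mu[1]], key=lambda r: (r.real, r.imag))
            got = sorted(roots[1:], key=lambda r: (r.real, r.imag))
            for a, b in zip(got, expect):
                assert a == pytest.approx(b, rel=1e-6)

    def test_decay_constants_decrease_toward_essential_spectrum(self):
        """For E1 < 2 E0 the modal decay times fall monotonically with n
        and approach tau_inf from above."""
        z = zener_c43(2.0)
        tau_inf = vp.zener_essential_spectrum(z)
        taus = [vp.zener_decay_constant(z, FIG_GEOM, n)
                for n in range(1, 40)]
        assert all(a > b for a, b in zip(taus, taus[1:]))
        assert all(t > tau_inf for t in taus)
        assert taus[-1] == pytest.approx(tau_inf, rel=1e-2)


class TestZenerSummaryConstants:
    @pytest.mark.parametrize("tau,expected,tol", [
        (2.0, 11.11, 5e-3), (0.2, 1.111, 5e-4), (0.05, 0.278, 5e-4),
    ])
    def test_essential_spectrum_values(self, tau, expected, tol):
        assert vp.zener_essential_spectrum(zener_c43(tau)) == \
            pytest.approx(expected, abs=tol)

    def test_essential_spectrum_branch_boundary(self):
        """E1 = 2 E0 makes both arguments of the min coincide."""
        z = vp.ZenerMaterial(E0=1.0e6, E1=2.0e6, tau=0.5)
        assert vp.zener_essential_spectrum(z) == \
            pytest.approx(3.0 * z.tau, rel=1e-12)

    def test_tau_eq_pdms_value_and_branch(self, pdms):
        """The silicone card has E1 < 2 E0, so tau_eq = 2 tau (E0+E1)/E1
        (about 1.701 s), inside the (2 tau, 3 tau) window."""
        te = vp.zener_tau_eq(pdms)
        assert te == pytest.approx(
            2 * pdms.tau * (pdms.E0 + pdms.E1) / pdms.E1, rel=1e-12)
        assert te == pytest.approx(1.701, abs=1e-3)

    def test_tau_eq_never_below_three_tau(self):
        """Both branches of the max() give tau_eq >= 3 tau, with
        equality exactly at the branch boundary E1 = 2 E0."""
        stiff = vp.ZenerMaterial(E0=3.0e6, E1=1.0e6, tau=0.1)  # E1 < 2E0
        assert vp.zener_tau_eq(stiff) > 3 * 0.1
        soft = vp.ZenerMaterial(E0=1.0e6, E1=5.0e6, tau=0.1)   # E1 >= 2E0
        assert vp.zener_tau_eq(soft) > 3 * 0.1
        boundary = vp.ZenerMaterial(E0=1.0e6, E1=2.0e6, tau=0.1)
        assert vp.zener_tau_eq(boundary) == pytest.approx(0.3, rel=1e-12)

    @pytest.mark.parametrize("tau,expected,ok", [
        (2.0, 100.0, True), (0.2, 1.0, True), (0.05, 0.0625, False),
    ])
    def test_validity_condition(self, tau, expected, ok):
        value, flag = vp.validity_condition(zener_c43(tau), FIG_GEOM)
        assert value == pytest.approx(expected, rel=1e-9)
        assert flag is ok


class TestAttenuation:
    def test_zero_length_attenuates_nothing(self):
        assert vp.attenuation(1.7, 13.8, 0.0).a == 0.0

    def test_pdms_first_meter(self, pdms, carotid):
        """Silicone carotid conduit damps about 4% per meter."""
        c = vp.wave_speeds_zener(pdms, carotid).c
        a = vp.attenuation(vp.zener_tau_eq(pdms), c, 1.0).a
        assert a == pytest.approx(0.04, abs=5e-3)

    def test_monotone_in_length(self):
        lengths = np.linspace(0.1, 50, 40)
        vals = [vp.attenuation(1.7, 13.8, L).a for L in lengths]
        assert all(x < y for x, y in zip(vals, vals[1:]))
        assert vp.attenuation(1.7, 13.8, 1e4).a == pytest.approx(1.0)

    def test_required_length_round_trip(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            tau_eq = 10.0 ** rng.uniform(-2, 1)
            c = 10.0 ** rng.uniform(0, 2)
            a = rng.uniform(1e-4, 0.999)
            L = vp.required_length(tau_eq, c, a)
            assert vp.attenuation(tau_eq, c, L).a == \
                pytest.approx(a, abs=1e-12)

    def test_required_length_small_target(self):
        assert vp.required_length(1.7, 13.8, 1e-9) < 1e-6

    def test_required_length_rejects_bad_target(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                vp.required_length(1.7, 13.8, bad)
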