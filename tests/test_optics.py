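import numpy as np
import pytest

from polspim import optics as op
from polspim import sphharm as sh


def sympy_cone_constants(na, n):
    """Independent closed-form oracle: integrate the (3/8pi) sin^2 emission
    pattern over the collection cone symbolically."""
    import sympy as sp

    theta, phi = sp.symbols("theta phi", positive=True)
    alpha = sp.asin(sp.Rational(0, 1) + sp.nsimplify(na) / sp.nsimplify(n))

    def eff(phi_d):
        mu = sp.Matrix([sp.sin(phi_d), 0, sp.cos(phi_d)])
        r = sp.Matrix([sp.sin(theta) * sp.cos(phi),
                       sp.sin(theta) * sp.sin(phi), sp.cos(theta)])
        integrand = (1 - (mu.dot(r)) ** 2) * sp.sin(theta)
        inner = sp.integrate(integrand, (phi, 0, 2 * sp.pi))
        return sp.Rational(3, 8) / sp.pi * sp.integrate(inner, (theta, 0, alpha))

    c1 = eff(0)
    c2 = sp.simplify(eff(sp.pi / 2) - c1)
    return float(c1), float(c2)


class TestExcitation:
    def test_parallel_perpendicular_45(self):
        z = np.array([0.0, 0.0, 1.0])
        x = np.array([1.0, 0.0, 0.0])
        assert op.excitation_weight(z, z) == 1.0
        assert op.excitation_weight(z, x) == 0.0
        d45 = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        assert op.excitation_weight(d45, z) == pytest.approx(0.5)

    def test_non_unit_raises(self):
        with pytest.raises(ValueError):
            op.excitation_weight([0, 0, 2.0], [0, 0, 1.0])


class TestDetectionConstants:
    def test_full_hemisphere_orientation_independent(self):
        c1, c2 = op.detection_constants(1.33, 1.33)
        assert c1 == pytest.approx(0.5, abs=1e-6)
        assert c2 == pytest.approx(0.0, abs=1e-6)

    def test_paraxial_limit(self):
        # C1 vanishes ~ alpha^4 while C2 ~ alpha^2: efficiency ~ C2 sin^2
        c1, c2 = op.detection_constants(0.01, 1.33)
        assert c1 < 1e-4 * c2

    @pytest.mark.parametrize("na", [1.1, 0.67])
    def test_against_symbolic_cone_integral(self, na):
        c1, c2 = op.detection_constants(na, 1.33)
        e1, e2 = sympy_cone_constants(na, 1.33)
        assert c1 == pytest.approx(e1, abs=1e-6)
        assert c2 == pytest.approx(e2, abs=1e-6)

    def test_na_above_n_raises(self):
        with pytest.raises(ValueError):
            op.detection_constants(1.5, 1.33)

    def test_collected_power_monotone_in_axial_angle(self, cfg):
        c1, c2 = op.detection_constants(cfg.na_a, cfg.n_medium)
        phis = np.linspace(0, np.pi / 2, 20)
        eff = c1 + c2 * np.sin(phis) ** 2
        assert np.all(np.diff(eff) >= 0)  # best in the transverse plane


class TestAngularResponse:
    def test_nonnegative_and_positive_signal(self, cfg):
        g = sh.sphere_grid()
        for spec in [op.MeasurementSpec("A", 0.7, 0.0),
                     op.MeasurementSpec("B", 1.9, 0.3)]:
            ar = op.angular_response(spec, cfg)
            w = ar.weight(g.dirs, cfg)
            assert np.all(w >= 0)
            assert g.integrate(w) > 0

    def test_exact_bandlimit(self, cfg):
        """Energy above l=4 is numerically zero: the weight is a product of
        two degree-2 polynomials in the direction."""
        big = sh.sphere_grid(24, 48)
        ar = op.angular_response(op.MeasurementSpec("A", 0.5, 0.35), cfg)
        w = ar.weight(big.dirs, cfg)
        w_band = sh.sh_evaluate(sh.sh_project(w, big), big)
        resid = big.integrate((w - w_band) ** 2) / big.integrate(w**2)
        assert resid < 1e-12

    def test_bisecting_dipole_ambiguity_untilted(self, cfg):
        d1 = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        d2 = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        for view in op.VIEWS:
            for psi in np.linspace(0, np.pi, 13):
                ar = op.angular_response(op.MeasurementSpec(view, float(psi)), cfg)
                assert ar.weight(d1, cfg) == pytest.approx(ar.weight(d2, cfg),
                                                           abs=1e-12)

    @pytest.mark.parametrize("tilt_deg", [10.0, 20.0])
    def test_tilt_breaks_ambiguity(self, cfg, tilt_deg):
        d1 = np.array([1.0, 0.0, 1.0]) / np.sqrt(2)
        d2 = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        spec = op.MeasurementSpec("A", np.pi / 4, np.deg2rad(tilt_deg))
        ar = op.angular_response(spec, cfg)
        w1, w2 = ar.weight(d1, cfg), ar.weight(d2, cfg)
        assert abs(w1 - w2) / max(w1, w2) > 0.01

    def test_polarization_perpendicular_to_propagation(self):
        for view in op.VIEWS:
            for tilt in (-0.3, 0.0, 0.4):
                spec = op.MeasurementSpec(view, 1.1, tilt)
                assert abs(spec.polarization() @ spec.propagation()) < 1e-12

    def test_photon_normalization_brightest_is_one(self, cfg):
        best = 0.0
        for view in op.VIEWS:
            for psi in np.linspace(0, np.pi, 91):
                ar = op.angular_response(op.MeasurementSpec(view, float(psi)), cfg)
                best = max(best, ar.coeffs[0] / np.sqrt(4 * np.pi))
        assert best == pytest.approx(1.0, abs=1e-9)


class TestDipolePSF:
    def test_axial_dipole_donut(self, cfg):
        psf = op.dipole_psf([0.0, 0.0, 1.0], cfg, "A")
        n = psf.intensity.shape[0]
        assert psf.intensity[n // 2, n // 2] < 0.05 * psf.intensity.max()

    def test_transverse_dipole_peaked_at_origin(self, cfg):
        psf = op.dipole_psf([1.0, 0.0, 0.0], cfg, "A")
        n = psf.intensity.shape[0]
        assert np.unravel_index(np.argmax(psf.intensity),
                                psf.intensity.shape) == (n // 2, n // 2)

    @pytest.mark.parametrize("frac", [0.0, 0.5, 1.0])
    def test_energy_matches_detection_constants(self, cfg, frac):
        """PSF integral equals C1 + C2 sin^2(phi_d) within 1%."""
        phi_d = frac * np.pi / 2
        mu = np.array([np.sin(phi_d), 0.0, np.cos(phi_d)])
        psf = op.dipole_psf(mu, cfg, "A")
        c1, c2 = op.detection_constants(cfg.na_a, cfg.n_medium)
        expected = c1 + c2 * np.sin(phi_d) ** 2
        assert psf.efficiency == pytest.approx(expected, rel=0.01)

    def test_energy_increases_with_na(self, cfg):
        mu = np.array([1.0, 0.0, 0.0])
        assert (op.dipole_psf(mu, cfg, "A").efficiency
                > op.dipole_psf(mu, cfg, "B").efficiency)


class TestTransferFunction:
    def test_support_cutoff(self, cfg):
        scheme = [op.MeasurementSpec("A", 0.0, 0.0)]
        tf = op.transfer_function(scheme, cfg, (16, 16, 16), 200.0)
        H = tf.measurement_h(0)
        outside = ~tf.support_mask(0)
        assert np.abs(H[:, outside]).max() == 0.0

    def test_dc_equality_factored_vs_coupled(self, cfg):
        """At zero frequency both fidelity modes reduce to the angular
        response integral."""
        for spec in [op.MeasurementSpec("A", 0.9, 0.0),
                     op.MeasurementSpec("B", 0.3, np.deg2rad(20))]:
            ar = op.angular_response(spec, cfg)
            H = op.coupled_transfer_2d(spec, cfg, n_grid=48)
            dc = H[:, 24, 24]
            assert np.abs(dc.imag).max() < 1e-9
            np.testing.assert_allclose(dc.real, ar.coeffs, atol=1e-6)

    def test_dc_signal_nonnegative_on_nonnegative_odf(self, cfg):
        g = sh.sphere_grid()
        rng = np.random.default_rng(0)
        A = op.angular_matrix([op.MeasurementSpec("A", 1.0, 0.2)], cfg)
        for _ in range(20):
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            vals = np.exp(3 * (g.dirs @ ax) ** 2)
            c = sh.sh_project(vals / g.integrate(vals), g)
            # band-limiting can produce small negative lobes; allow tiny slack
            assert (A @ c)[0] > -1e-9

    def test_tilt_beyond_max_raises(self, cfg):
        spec = op.MeasurementSpec("A", 0.0, np.deg2rad(60))
        with pytest.raises(ValueError, match="tilt"):
            op.transfer_function([spec], cfg, (8, 8, 8), 200.0)

    def test_empty_scheme_raises(self, cfg):
        with pytest.raises(ValueError):
            op.transfer_function([], cfg, (8, 8, 8), 200.0)

    def test_coarse_grid_warns(self, cfg):
        import warnings as w

        with w.catch_warnings(record=True) as rec:
            w.simplefilter("always")
            op.scalar_otf(cfg, "A", (8, 8, 8), 300.0)
        assert any("too coarse" in str(r.message) for r in rec)
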