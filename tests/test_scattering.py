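"""Debye profiles, Guinier, Kratky, P(r), Porod mass and chi-square."""

import numpy as np
import pytest

from jiptandem import model_builder as mb
from jiptandem import scattering as sc
from jiptandem import synthetic_data as sd


def point_structure(coords):
    coords = np.asarray(coords, float)
    n = len(coords)
    return mb.Structure(np.array(["A"] * n), np.arange(1, n + 1),
                        np.array(["ALA"] * n), np.array(["CA"] * n), coords)


def sphere_curve(q, radius):
    x = q * radius
    amp = np.ones_like(x)
    nz = x > 1e-9
    amp[nz] = 3 * (np.sin(x[nz]) - x[nz] * np.cos(x[nz])) / x[nz] ** 3
    return sc.ScatteringCurve(q, amp ** 2)


class TestDebye:
    def test_zero_angle_limit(self, model):
        q = np.array([0.0, 0.01])
        c = sc.debye_intensity(model, q, method="direct")
        _, w = sc.scattering_centers(model)
        assert c.I[0] == pytest.approx(w.sum() ** 2, rel=1e-12)

    def test_two_centers_closed_form(self):
        d = 17.0
        s = point_structure([[0, 0, 0], [0, 0, d]])
        q = np.linspace(0.01, 0.5, 200)
        c = sc.debye_intensity(s, q, form_factors=np.ones(2), method="direct",
                               residue_sphere_radius=1e-9)
        expect = 2.0 * (1.0 + np.sin(q * d) / (q * d))
        assert np.allclose(c.I, expect, rtol=1e-10)

    def test_histogram_matches_direct(self, model):
        """Accelerated path agrees with the exact double sum to <0.5%."""
        q = np.linspace(0.008, 0.5, 120)
        hist = sc.debye_intensity(model, q, method="histogram")
        direct = sc.debye_intensity(model, q, method="direct")
        assert np.max(np.abs(hist.I / direct.I - 1.0)) < 0.005

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            sc.debye_intensity(point_structure(np.empty((0, 3))),
                               np.linspace(0.01, 0.1, 10))

    def test_debye_reciprocity_via_pr(self, model, model_curve):
        """P(r) + forward transform reproduces the Debye curve shape."""
        pr = sc.pr_from_structure(model, bin_width=0.25)
        q = model_curve.q
        i_pr = sc.pr_forward_intensity(pr, q)
        i_pr = i_pr / i_pr[0]
        amp = sc._sphere_amplitude(q, sc.DEFAULT_RESIDUE_SPHERE_RADIUS) ** 2
        i_ref = model_curve.I / model_curve.I[0] / amp
        # distinct-pair part only: remove the constant self term
        _, w = sc.scattering_centers(model)
        self_frac = (w ** 2).sum() / w.sum() ** 2
        i_ref = (i_ref - self_frac) / (1 - self_frac)
        m = q <= 0.5
        assert np.max(np.abs(i_pr[m] - i_ref[m]) / np.abs(i_ref[m]).max()) < 0.01


class TestGuinier:
    def test_exact_guinier_law(self):
        q = np.linspace(0.0085, 0.018, 40)
        rg, i0 = 63.4, 100.0
        c = sc.ScatteringCurve(q, i0 * np.exp(-(q * rg) ** 2 / 3.0))
        g = sc.guinier_fit(c, qmin=0.0085, qmax=0.018)
        assert g.Rg == pytest.approx(rg, rel=1e-6)
        assert g.I0 == pytest.approx(i0, rel=1e-6)

    def test_sphere_limit(self):
        R = 30.0
        q = np.linspace(1e-4, 0.02, 300)
        g = sc.guinier_fit(sphere_curve(q, R), qmin=1e-4, qmax=0.01)
        assert g.Rg == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.01)

    def test_recovery_on_globular_simulation(self, model):
        """Noiseless simulation of the compact bundle: Rg back within 2%."""
        bundle = model.select(resrange=(26, 73))
        curve = sc.debye_intensity(bundle, np.linspace(0.008, 0.5, 500))
        g = sc.guinier_fit(curve)
        centers, w = sc.scattering_centers(bundle)
        cm = np.average(centers, axis=0, weights=w)
        rg_true = np.sqrt(np.average(((centers - cm) ** 2).sum(1), weights=w)
                          + 0.6 * sc.DEFAULT_RESIDUE_SPHERE_RADIUS ** 2)
        assert g.Rg == pytest.approx(rg_true, rel=0.02)

    def test_rod_underestimates_as_expected(self, model_curve, model):
        """Elongated particles: the Guinier window bias is negative and
        grows with the window, the textbook behaviour that also separates
        the measured Guinier and P(r) Rg values."""
        g_tight = sc.guinier_fit(model_curve, qrg_limit=0.7)
        g_wide = sc.guinier_fit(model_curve, qrg_limit=1.3)
        rg_true = mb.radius_of_gyration(model)
        assert g_wide.Rg < g_tight.Rg < rg_true
        assert g_tight.Rg == pytest.approx(rg_true, rel=0.06)

    def test_nonpositive_intensity_rejected(self):
        q = np.linspace(0.01, 0.1, 30)
        c = sc.ScatteringCurve(q, np.linspace(1.0, -0.1, 30))
        with pytest.raises(ValueError):
            sc.guinier_fit(c, qmin=0.01, qmax=0.1)


class TestKratky:
    def test_guinier_law_peak_analytic(self):
        """The globular reference peaks at exactly (sqrt(3), 3/e)."""
        q = np.linspace(1e-4, 0.2, 20001)
        rg = 30.0
        c = sc.ScatteringCurve(q, np.exp(-(q * rg) ** 2 / 3.0))
        _, _, (u_peak, k_peak) = sc.dimensionless_kratky(c, rg, 1.0)
        assert u_peak == pytest.approx(np.sqrt(3.0), abs=2e-3)
        assert k_peak == pytest.approx(3.0 / np.e, abs=1e-4)

    def test_flat_curve_has_no_interior_peak(self):
        q = np.linspace(0.001, 0.3, 500)
        c = sc.ScatteringCurve(q, np.ones_like(q))
        u, k, (u_peak, _) = sc.dimensionless_kratky(c, 30.0, 1.0)
        assert np.all(np.diff(k) > 0)
        assert u_peak == pytest.approx(u[-1])

    def test_model_curve_shows_elongation(self, model_curve):
        """The rod-like tandem peaks far above/later than the globular
        reference (the coarse model overshoots the measured peak; see the
        methods note on cross-section thickness)."""
        g = sc.guinier_fit(model_curve, qrg_limit=0.7)
        _, _, (u_peak, k_peak) = sc.dimensionless_kratky(model_curve, g.Rg, g.I0)
        assert u_peak > 5.0
        assert k_peak > 3.0


class TestPairDistribution:
    def test_two_centers_single_bin(self):
        s = point_structure([[0, 0, 0], [0, 0, 25.0]])
        pr = sc.pr_from_structure(s)
        assert pr.mode_r == pytest.approx(25.0, abs=0.5)
        assert pr.Dmax == pytest.approx(25.0)

    def test_rod_like_profile(self, model):
        pr = sc.pr_from_structure(model)
        # long-rod signature: early mode, long tail
        assert pr.mode_r < 0.2 * pr.Dmax
        assert pr.Dmax == pytest.approx(mb.max_extent(model), abs=1.0)

    def test_pr_rg_matches_coordinates(self, model):
        pr = sc.pr_from_structure(model, bin_width=0.25)
        centers, w = sc.scattering_centers(model)
        cm = np.average(centers, axis=0, weights=w)
        rg = np.sqrt(np.average(((centers - cm) ** 2).sum(1), weights=w))
        assert pr.Rg == pytest.approx(rg, rel=0.01)

    def test_single_center_rejected(self):
        with pytest.raises(ValueError):
            sc.pr_from_structure(point_structure([[0, 0, 0]]))


class TestIFT:
    def test_round_trip_known_pr(self):
        """Data simulated from a known smooth p(r) is inverted within 5% L2."""
        R = 40.0
        r = np.linspace(0.0, 2 * R, 201)
        x = r / (2 * R)
        p = r ** 2 * (1.0 - 1.5 * x + 0.5 * x ** 3)
        p /= np.trapezoid(p, r)
        truth = sc.PairDistribution(r=r, p=p, Dmax=2 * R)
        q = np.linspace(0.008, 0.5, 500)
        I = sc.pr_forward_intensity(truth, q)
        sigma = 0.01 * np.abs(I) + 1e-4 * I[0]
        rng = np.random.default_rng(2)
        data = sc.ScatteringCurve(q, I + rng.normal(0.0, sigma), sigma)
        ift = sc.ift_pr(data, Dmax=2 * R)
        pt = np.interp(ift.r, r, p)
        pt /= np.trapezoid(pt, ift.r)
        pi = ift.p / np.trapezoid(ift.p, ift.r)
        l2 = np.sqrt(np.trapezoid((pi - pt) ** 2, ift.r)
                     / np.trapezoid(pt ** 2, ift.r))
        assert l2 < 0.05
        assert ift.Rg == pytest.approx(truth.Rg, rel=0.02)

    def test_two_point_concentrates_at_distance(self):
        d = 50.0
        q = np.linspace(0.008, 0.5, 400)
        I = 2.0 * (1.0 + np.sinc(q * d / np.pi))
        data = sc.ScatteringCurve(q, I, np.full_like(q, 0.01 * I[0]))
        ift = sc.ift_pr(data, Dmax=60.0)
        # ignore the r->0 bins that absorb the constant self term
        far = ift.r > 5.0
        assert ift.r[far][np.argmax(ift.p[far])] == pytest.approx(d, abs=2.0)

    def test_needs_uncertainties(self):
        q = np.linspace(0.01, 0.3, 50)
        with pytest.raises(ValueError):
            sc.ift_pr(sc.ScatteringCurve(q, np.ones_like(q)), Dmax=50.0)


class TestPorodMass:
    def test_sphere_apparent_volume(self):
        """Apparent Porod volume of a protein-scale solid sphere within 5%."""
        for R in (40.0, 50.0):
            q = np.linspace(0.002, 0.5, 2000)
            c = sphere_curve(q, R)
            g = sc.guinier_fit(c, qmin=0.002, qmax=0.6 / R)
            est = sc.porod_mow_mass(c, g)
            v_true = 4.0 / 3.0 * np.pi * R ** 3
            assert est.apparent_volume == pytest.approx(v_true, rel=0.05)

    def test_simulated_dimer_mass(self, model_curve):
        """Mass from the simulated dimer curve within 10% of 2 x 20.3 kDa."""
        g = sc.guinier_fit(model_curve, qrg_limit=0.7)
        est = sc.porod_mow_mass(model_curve, g)
        assert est.mass_kda == pytest.approx(40.6, rel=0.10)

    def test_scale_invariance(self, model_curve):
        g1 = sc.guinier_fit(model_curve, qrg_limit=0.7)
        scaled = sc.ScatteringCurve(model_curve.q, model_curve.I * 37.0)
        g2 = sc.guinier_fit(scaled, qrg_limit=0.7)
        m1 = sc.porod_mow_mass(model_curve, g1)
        m2 = sc.porod_mow_mass(scaled, g2)
        assert m1.mass_kda == pytest.approx(m2.mass_kda, rel=1e-4)

    def test_short_curve_rejected(self, model_curve):
        short = sc.ScatteringCurve(model_curve.q[:100], model_curve.I[:100])
        g = sc.guinier_fit(short, qrg_limit=0.7)
        with pytest.raises(ValueError):
            sc.porod_mow_mass(short, g)


class TestChi2:
    def test_identical_curves(self, model_curve):
        data = sc.ScatteringCurve(model_curve.q, model_curve.I,
                                  np.full(len(model_curve), 1.0))
        chi2, scale = sc.chi2_fit(data, model_curve)
        assert chi2 == pytest.approx(0.0, abs=1e-18)
        assert scale == pytest.approx(1.0)

    def test_noisy_scaled_data(self, model_curve, rng):
        """data = 2 x model + unit-sigma noise: scale ~2, chi^2 ~1."""
        n = len(model_curve)
        I0 = model_curve.I / model_curve.I[0] * 1e4   # noise small vs signal
        noise = rng.normal(0.0, 1.0, n)
        data = sc.ScatteringCurve(model_curve.q, 2.0 * I0 + noise, np.ones(n))
        base = sc.ScatteringCurve(model_curve.q, I0)
        chi2, scale = sc.chi2_fit(data, base)
        assert scale == pytest.approx(2.0, rel=0.01)
        assert chi2 == pytest.approx(1.0, abs=0.1)

    def test_model_rescaling_invariance(self, model_curve, rng):
        n = len(model_curve)
        data = sc.ScatteringCurve(model_curve.q,
                                  model_curve.I * (1 + 0.01 * rng.normal(size=n)),
                                  0.01 * model_curve.I)
        c1, _ = sc.chi2_fit(data, model_curve)
        c2, _ = sc.chi2_fit(data, sc.ScatteringCurve(model_curve.q,
                                                     model_curve.I * 123.4))
        assert c1 == pytest.approx(c2, rel=1e-9)

    def test_grid_mismatch_rejected(self, model_curve):
        data = sc.ScatteringCurve(np.linspace(0.001, 0.6, 50),
                                  np.ones(50), np.ones(50))
        with pytest.raises(ValueError):
            sc.chi2_fit(data, model_curve)


class TestCurveIO:
    def test_ascii_round_trip(self, tmp_path, model_curve):
        data = sc.ScatteringCurve(model_curve.q, model_curve.I,
                                  0.01 * np.abs(model_curve.I) + 1e-12)
        p = tmp_path / "curve.dat"
        sc.write_curve(data, p)
        back = sc.read_curve(p)
        assert np.allclose(back.q, data.q)
        assert np.allclose(back.I, data.I)
        assert np.allclose(back.sigma, data.sigma)

    def test_nm_unit_conversion(self, tmp_path):
        p = tmp_path / "nm.dat"
        p.write_text("# q I sigma\n0.1 5.0 0.1\n0.2 4.0 0.1\n")
        c = sc.read_curve(p, q_unit="nm^-1")
        assert c.q[0] == pytest.approx(0.01)
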