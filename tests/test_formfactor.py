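"""Analytical form factor: closed-form limits, oracles, polydispersity, p(r)."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import j1

from nanodisc.composition import MolecularComposition, component_slds
from nanodisc.curves import ScatteringCurve
from nanodisc.formfactor import (FM2_TO_CM2, discretize_model,
                                 bead_scattering_lengths, model_intensity,
                                 model_pr, polydisperse_intensity,
                                 pr_to_intensity)
from nanodisc.geometry import NanodiscParams, derive_dimensions

COMP = MolecularComposition()
DH5ISH = dict(a_head=52.0, eps=1.4, n_lipid=102.0)


def circular_core_shell_intensity(q, params, comp):
    """Independent 1-D quadrature for the circular (eps = 1) disc model.

    Written directly from the circular core-shell cylinder form factor with
    scipy.integrate.quad; shares no code with the package's 2-D orientation
    average.
    """
    d = derive_dimensions(params, comp)
    slds = component_slds(comp, "xray", "h2o")
    r_core, r_out = d.r_major, d.r_major + d.w_belt
    terms = [
        (slds["tails"], math.pi * r_core**2 * d.h_tails, r_core, d.h_tails, None),
        (slds["head"], math.pi * r_core**2 * 2 * d.d_head, r_core, d.h_lipid,
         d.h_tails),
        (slds["belt"], math.pi * (r_out**2 - r_core**2) * params.h_belt, r_out,
         params.h_belt, (r_core, params.h_belt)),
    ]

    def disc_amp(qv, radius, height, alpha):
        u = qv * radius * math.sin(alpha)
        w = qv * height * math.cos(alpha) / 2
        fu = 1.0 if u < 1e-9 else 2 * j1(u) / u
        fw = 1.0 if abs(w) < 1e-9 else math.sin(w) / w
        return fu * fw

    out = []
    for qv in q:
        def integrand(alpha):
            amp = 0.0
            for drho, vol, radius, height, extra in terms:
                if extra is None:
                    amp += drho * vol * disc_amp(qv, radius, height, alpha)
                elif isinstance(extra, tuple):  # hollow cylinder
                    r_in, h = extra
                    v_out = math.pi * radius**2 * h
                    v_in = math.pi * r_in**2 * h
                    amp += drho * vol * (
                        v_out * disc_amp(qv, radius, h, alpha)
                        - v_in * disc_amp(qv, r_in, h, alpha)) / (v_out - v_in)
                else:  # head pair: full cylinder minus tail cylinder
                    h_out, h_in = height, extra
                    v_out = math.pi * radius**2 * h_out
                    v_in = math.pi * radius**2 * h_in
                    amp += drho * vol * (
                        v_out * disc_amp(qv, radius, h_out, alpha)
                        - v_in * disc_amp(qv, radius, h_in, alpha)) / (v_out - v_in)
            return amp**2 * math.sin(alpha)
        val, _ = quad(integrand, 0, math.pi / 2, limit=200)
        out.append(val)
    return FM2_TO_CM2 * np.array(out)


class TestModelIntensity:
    def test_forward_scattering_closed_form(self):
        p = NanodiscParams(**DH5ISH, sigma_r=0.0, background=0.0)
        d = derive_dimensions(p, COMP)
        slds = component_slds(COMP, "xray", "h2o")
        v_tail = math.pi * d.r_major * d.r_minor * d.h_tails
        v_head = math.pi * d.r_major * d.r_minor * 2 * d.d_head
        total = (slds["tails"] * v_tail + slds["head"] * v_head
                 + slds["belt"] * 2 * COMP.belt.volume)
        got = model_intensity(np.array([1e-6, 1e-5]), p, COMP).intensity[0]
        assert got == pytest.approx(FM2_TO_CM2 * total**2, rel=1e-6)

    def test_circular_limit_matches_independent_quadrature(self):
        p = NanodiscParams(a_head=52.0, eps=1.0, n_lipid=102.0, sigma_r=0.0)
        q = np.linspace(0.01, 0.25, 20)
        ours = model_intensity(q, p, COMP).intensity
        oracle = circular_core_shell_intensity(q, p, COMP)
        np.testing.assert_allclose(ours, oracle, rtol=1e-4)

    def test_first_minimum_near_007(self):
        """Core-shell X-ray contrast puts the first minimum near 0.07 1/A."""
        q = np.linspace(0.02, 0.15, 200)
        i = model_intensity(q, NanodiscParams(**DH5ISH), COMP).intensity
        k = next(k for k in range(1, len(q) - 1) if i[k] < i[k - 1] and i[k] < i[k + 1])
        assert 0.05 <= q[k] <= 0.09

    def test_sans_bulk_contrast_monotone(self):
        q = np.linspace(0.0087, 0.17, 60)
        i = model_intensity(q, NanodiscParams(**DH5ISH), COMP,
                            contrast="neutron").intensity
        assert np.all(np.diff(i) < 0)

    def test_intensity_above_background(self):
        p = NanodiscParams(**DH5ISH, background=1e-3)
        q = np.linspace(0.01, 0.4, 80)
        assert np.all(model_intensity(q, p, COMP).intensity >= 1e-3)

    def test_continuity_in_parameters(self):
        q = np.linspace(0.01, 0.25, 30)
        base = model_intensity(q, NanodiscParams(**DH5ISH), COMP).intensity
        for name, delta in (("eps", 1e-5), ("a_head", 1e-4), ("n_lipid", 1e-4)):
            kw = dict(DH5ISH)
            kw[name] += delta
            pert = model_intensity(q, NanodiscParams(**kw), COMP).intensity
            assert np.max(np.abs(pert - base) / base) < 1e-3

    def test_tags_increase_forward_scattering(self):
        q = np.array([1e-5, 0.01])
        p = NanodiscParams(**DH5ISH)
        plain = model_intensity(q, p, COMP, n_tags=0).intensity[0]
        tagged = model_intensity(q, p, COMP, n_tags=2).intensity[0]
        slds = component_slds(COMP, "xray", "h2o")
        beta = slds["tag"] * COMP.tag.volume
        assert tagged > plain
        # I(0) = (sum drho V + 2 beta)^2
        assert math.sqrt(tagged / FM2_TO_CM2) == pytest.approx(
            math.sqrt(plain / FM2_TO_CM2) + 2 * beta, rel=1e-5)

    def test_bad_qgrid_rejected(self):
        with pytest.raises(ValueError):
            model_intensity(np.array([0.2, 0.1]), NanodiscParams(**DH5ISH), COMP)


class TestPolydispersity:
    def test_zero_sigma_identical(self):
        q = np.linspace(0.01, 0.25, 30)
        p = NanodiscParams(**DH5ISH, sigma_lip=0.0)
        np.testing.assert_array_equal(
            polydisperse_intensity(q, p, COMP).intensity,
            model_intensity(q, p, COMP).intensity)

    def test_one_percent_polydispersity_small_effect(self):
        q = np.linspace(0.01, 0.25, 40)
        mono = model_intensity(q, NanodiscParams(**DH5ISH), COMP).intensity
        poly = polydisperse_intensity(
            q, NanodiscParams(**DH5ISH, sigma_lip=0.01), COMP).intensity
        assert np.max(np.abs(poly - mono) / mono) < 0.01

    def test_quadrature_matches_dense_average(self):
        """Gauss-Hermite vs a 161-point trapezoidal average over N_lipid."""
        q = np.linspace(0.01, 0.25, 25)
        sig = 0.05
        p = NanodiscParams(**DH5ISH, sigma_lip=sig)
        gh = polydisperse_intensity(q, p, COMP).intensity
        n_bar = DH5ISH["n_lipid"]
        sd = sig * n_bar
        grid = np.linspace(n_bar - 4 * sd, n_bar + 4 * sd, 161)
        pdf = np.exp(-0.5 * ((grid - n_bar) / sd) ** 2)
        pdf /= np.trapezoid(pdf, grid)
        dense = np.zeros_like(q)
        for n_l, w in zip(grid, pdf * np.gradient(grid)):
            kw = dict(DH5ISH)
            kw["n_lipid"] = n_l
            dense += w * model_intensity(q, NanodiscParams(**kw), COMP).intensity
        np.testing.assert_allclose(gh, dense, rtol=2e-3)

    def test_polydispersity_fills_first_minimum(self):
        q = np.linspace(0.02, 0.15, 150)
        depths = []
        for sig in (0.0, 0.03, 0.06, 0.09):
            i = polydisperse_intensity(
                q, NanodiscParams(**DH5ISH, sigma_lip=sig), COMP).intensity
            k = next(k for k in range(1, len(q) - 1)
                     if i[k] < i[k - 1] and i[k] < i[k + 1])
            depths.append(i[k])
        assert all(np.diff(depths) > 0)


class TestPairDistance:
    def test_same_sign_contrast_gives_nonnegative_pr(self):
        p = NanodiscParams(**DH5ISH, sigma_r=0.0)
        r, pr = model_pr(p, COMP, contrast="neutron", spacing=2.5)
        assert pr.min() >= 0

    def test_xray_core_shell_gives_negative_lobe(self):
        p = NanodiscParams(**DH5ISH, sigma_r=0.0)
        r, pr = model_pr(p, COMP, contrast="xray", spacing=2.5)
        neg = r[pr < 0]
        assert len(neg) and neg.min() < 40.0

    def test_pr_vanishes_beyond_dmax(self):
        p = NanodiscParams(**DH5ISH, sigma_r=0.0)
        d = derive_dimensions(p, COMP)
        d_max = math.hypot(2 * (d.r_major + d.w_belt), d.h_lipid)
        r, pr = model_pr(p, COMP, spacing=2.5)
        assert np.all(np.abs(pr[r > d_max + 3.0]) == 0)

    def test_transform_consistency_with_intensity(self):
        p = NanodiscParams(**DH5ISH, sigma_r=0.0)
        r, pr = model_pr(p, COMP, contrast="xray", spacing=1.75)
        q = np.linspace(0.01, 0.2, 25)
        i_pr = pr_to_intensity(r, pr, q) * FM2_TO_CM2
        i_an = model_intensity(q, p, COMP).intensity
        assert np.max(np.abs(i_pr - i_an) / i_an) < 0.03

    def test_coarse_spacing_rejected(self):
        with pytest.raises(ValueError):
            discretize_model(NanodiscParams(**DH5ISH), COMP, spacing=3.5)
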