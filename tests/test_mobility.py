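"""Unit tests for mobilogram deconvolution."""

import numpy as np
import pytest

from oligoms.mobility import (
    GaussianComponent,
    Mobilogram,
    MobilogramFit,
    fit_mobilogram,
    gaussian_fwhm,
    peak_width_stats,
    relative_contributions,
)
from oligoms.synthetic import make_mobilogram


class TestGaussianShape:
    def test_unit_area(self):
        x = np.linspace(-50, 50, 200001)
        y = gaussian_fwhm(x, 0.0, 2.0, 1.0)
        assert np.trapezoid(y, x) == pytest.approx(1.0, rel=1e-8)

    def test_fwhm_definition(self):
        w = 1.6
        peak = gaussian_fwhm(np.array([0.0]), 0.0, w, 1.0)[0]
        half = gaussian_fwhm(np.array([w / 2]), 0.0, w, 1.0)[0]
        assert half == pytest.approx(peak / 2, rel=1e-12)

    def test_area_scales_linearly(self):
        x = np.linspace(-10, 10, 5001)
        y1 = gaussian_fwhm(x, 0.0, 1.0, 1.0)
        y3 = gaussian_fwhm(x, 0.0, 1.0, 3.0)
        assert np.allclose(y3, 3 * y1)


class TestMobilogramValidation:
    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            Mobilogram(np.arange(5.0), np.ones(5))

    def test_nonmonotone_axis_rejected(self):
        x = np.array([0, 1, 2, 2, 3, 4, 5, 6], dtype=float)
        with pytest.raises(ValueError, match="strictly increasing"):
            Mobilogram(x, np.ones(8))

    def test_negative_intensity_rejected(self):
        y = np.ones(10)
        y[3] = -0.1
        with pytest.raises(ValueError):
            Mobilogram(np.arange(10.0), y)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Mobilogram(np.arange(10.0), np.ones(9))


class TestFitRecovery:
    def test_noiseless_two_component_recovery(self):
        truth = [GaussianComponent(4.0, 0.8, 10.0),
                 GaussianComponent(6.5, 1.1, 5.0)]
        mob = make_mobilogram(truth, k_im=0.3)
        fit = fit_mobilogram(mob, n_components=2)
        assert fit.converged
        assert fit.k_im == pytest.approx(0.3, rel=1e-6)
        for got, want in zip(fit.components, truth):
            assert got.x_c == pytest.approx(want.x_c, rel=1e-6)
            assert got.w == pytest.approx(want.w, rel=1e-6)
            assert got.A == pytest.approx(want.A, rel=1e-6)

    def test_refit_from_solution_is_stable(self):
        truth = [GaussianComponent(5.0, 0.8, 4.0)]
        mob = make_mobilogram(truth, k_im=0.1)
        fit1 = fit_mobilogram(mob, n_components=1)
        fit2 = fit_mobilogram(
            mob, n_components=1,
            init=[(c.x_c, c.w, c.A) for c in fit1.components],
        )
        assert abs(fit2.rss - fit1.rss) < 1e-10

    def test_aicc_selects_true_component_count(self, rng):
        truth = [GaussianComponent(4.0, 0.8, 10.0),
                 GaussianComponent(7.0, 0.8, 6.0)]
        mob = make_mobilogram(truth, noise_sd=0.02, rng=rng)
        fit = fit_mobilogram(mob)  # automatic selection
        big = [c for c in fit.components
               if c.A > 0.05 * sum(k.A for k in fit.components)]
        assert len(big) == 2

    def test_components_sorted_by_center(self, rng):
        truth = [GaussianComponent(8.0, 0.8, 5.0),
                 GaussianComponent(3.0, 0.8, 5.0)]
        mob = make_mobilogram(truth, noise_sd=0.01, rng=rng)
        fit = fit_mobilogram(mob, n_components=2)
        centers = [c.x_c for c in fit.components]
        assert centers == sorted(centers)

    def test_too_many_components_for_data_rejected(self):
        mob = Mobilogram(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError, match="points"):
            fit_mobilogram(mob, n_components=2)

    def test_invalid_component_count_rejected(self):
        mob = make_mobilogram([GaussianComponent(5.0, 0.8, 1.0)])
        with pytest.raises(ValueError):
            fit_mobilogram(mob, n_components=0)

    def test_predict_reproduces_model(self):
        fit = MobilogramFit(
            k_im=0.2,
            components=[GaussianComponent(5.0, 1.0, 2.0)],
            rss=0.0, converged=True,
        )
        x = np.linspace(0, 10, 101)
        expect = 0.2 + gaussian_fwhm(x, 5.0, 1.0, 2.0)
        assert np.allclose(fit.predict(x), expect)


class TestContributions:
    def test_fractions_sum_to_one(self, rng):
        truth = [GaussianComponent(4.0, 0.8, 6.0),
                 GaussianComponent(7.0, 0.8, 3.0)]
        mob = make_mobilogram(truth, noise_sd=0.01, rng=rng)
        fit = fit_mobilogram(mob, n_components=2)
        frac = relative_contributions(fit)
        assert sum(frac.values()) == pytest.approx(1.0)
        assert frac["g1"] == pytest.approx(2 / 3, abs=0.02)

    def test_labelled_components_grouped(self):
        fit = MobilogramFit(
            k_im=0.0,
            components=[
                GaussianComponent(3.0, 1.0, 1.0, label="D"),
                GaussianComponent(5.0, 1.0, 1.0, label="M"),
                GaussianComponent(7.0, 1.0, 2.0, label="M"),
            ],
            rss=0.0, converged=True,
        )
        frac = relative_contributions(fit)
        assert frac == pytest.approx({"D": 0.25, "M": 0.75})

    def test_unconverged_fit_rejected(self):
        fit = MobilogramFit(k_im=0.0,
                            components=[GaussianComponent(3.0, 1.0, 1.0)],
                            rss=1.0, converged=False)
        with pytest.raises(ValueError, match="converge"):
            relative_contributions(fit)


class TestPeakWidthStats:
    def _fits(self, widths):
        return [
            MobilogramFit(
                k_im=0.0,
                components=[GaussianComponent(5.0, w, 1.0, label="D")],
                rss=0.0, converged=True,
            )
            for w in widths
        ]

    def test_wider_group_detected(self):
        out = peak_width_stats(
            self._fits([0.80, 0.82, 0.78]),
            self._fits([1.20, 1.25, 1.18]),
            species="D",
        )
        assert out["mean_w_b"] > out["mean_w_a"]
        assert out["p"] < 0.01

    def test_identical_groups_not_significant(self):
        out = peak_width_stats(self._fits([0.8, 0.8]),
                               self._fits([0.8, 0.8]), species="D")
        assert out["p"] == 1.0 and out["t"] == 0.0

    def test_missing_species_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            peak_width_stats(self._fits([0.8, 0.8]),
                             self._fits([0.8, 0.8]), species="Tr")
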