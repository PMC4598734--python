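"""Unit tests for the synthetic data generators."""

import numpy as np
import pytest

from oligoms.constants import C13_C12_DELTA
from oligoms.ion_grid import oligomer_mz
from oligoms.synthetic import (
    GroundTruth,
    default_ground_truth,
    make_calibration_set,
    make_mobilogram,
    make_spectrum,
    mobilogram_for_channel,
)
from oligoms.mobility import GaussianComponent


class TestGroundTruth:
    def test_default_distribution_sums_to_one(self):
        truth = default_ground_truth()
        assert sum(truth.distribution.values()) == pytest.approx(1.0)
        assert set(truth.distribution) == {"M", "D", "Tr", "Te", "P", "Hx"}

    def test_bad_distribution_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GroundTruth(distribution={"M": 0.5, "D": 0.4})

    def test_json_round_trip(self):
        truth = default_ground_truth(seed=5)
        back = GroundTruth.from_json(truth.to_json())
        assert back == truth

    def test_size_scaling(self):
        truth = default_ground_truth()
        assert truth.oligomer_ccs(1) == pytest.approx(truth.ccs_monomer)
        assert truth.oligomer_ccs(8) == pytest.approx(4 * truth.ccs_monomer)

    def test_drift_time_consistent_with_calibration(self):
        # the drift time the generator emits must invert through the
        # same power law the calibration stage fits
        from oligoms.calibration import fit_calibration, ccs_from_drift

        truth = default_ground_truth()
        cal = fit_calibration(
            make_calibration_set(truth.cal_scale, truth.cal_exponent,
                                 truth.cal_c),
            gas=truth.gas, c=truth.cal_c,
        )
        mz = oligomer_mz(truth.species, 2, 5)
        td = truth.drift_time_for(2, 5, mz)
        mass = mz * 5 - 5 * 1.007276
        omega = ccs_from_drift(cal, td, 5, mass, extrapolate=True)
        assert omega == pytest.approx(truth.oligomer_ccs(2), rel=1e-6)


class TestMakeSpectrum:
    def test_deterministic_given_seed(self):
        a = make_spectrum(default_ground_truth(seed=3))
        b = make_spectrum(default_ground_truth(seed=3))
        assert [c.mz for c in a.channels] == [c.mz for c in b.channels]
        assert [c.intensity for c in a.channels] == [
            c.intensity for c in b.channels
        ]

    def test_quadruplet_channel_merged(self):
        spec = make_spectrum(default_ground_truth())
        degenerate = [c for c in spec.channels if len(c.ions) == 4]
        assert len(degenerate) == 1
        ch = degenerate[0]
        assert {(n, z) for _, n, z in ch.ions} == {
            (1, 2), (2, 4), (3, 6), (4, 8)
        }
        assert ch.spacing is None  # congested channel: unreadable

    def test_isolated_channel_carries_spacing(self):
        spec = make_spectrum(default_ground_truth())
        iso = [c for c in spec.channels if len(c.ions) == 1]
        assert iso
        for ch in iso:
            _, _, z = ch.ions[0]
            if ch.spacing is not None:
                assert ch.spacing == pytest.approx(C13_C12_DELTA / z)

    def test_contributor_fractions_sum_to_one(self):
        spec = make_spectrum(default_ground_truth())
        for ch in spec.channels:
            assert sum(ch.contributors.values()) == pytest.approx(1.0)

    def test_mz_range_respected(self):
        spec = make_spectrum(default_ground_truth(),
                             mz_range=(1500.0, 2500.0))
        assert all(1500.0 <= c.mz <= 2500.0 for c in spec.channels)

    def test_noiseless_intensities_exact(self):
        truth = default_ground_truth()
        spec = make_spectrum(truth, noise_frac=0.0)
        iso = {(c.ions[0][1], c.ions[0][2]): c.intensity
               for c in spec.channels if len(c.ions) == 1}
        # D+5 intensity = pop(D) * weight(z=5)
        assert iso[(2, 5)] == pytest.approx(0.30 * 0.5)

    def test_peak_list_shape(self):
        spec = make_spectrum(default_ground_truth())
        rows = spec.peak_list()
        assert all(len(r) == 3 for r in rows)


class TestMakeMobilogram:
    def test_noiseless_trace_matches_model(self):
        comp = GaussianComponent(5.0, 0.8, 2.0)
        mob = make_mobilogram([comp], k_im=0.1)
        from oligoms.mobility import gaussian_fwhm

        expect = 0.1 + gaussian_fwhm(mob.drift_time, 5.0, 0.8, 2.0)
        assert np.allclose(mob.intensity, expect)

    def test_noise_clipped_nonnegative(self, rng):
        mob = make_mobilogram([GaussianComponent(5.0, 0.8, 0.01)],
                              noise_sd=0.5, rng=rng)
        assert np.all(mob.intensity >= 0)

    def test_bad_axis_rejected(self):
        with pytest.raises(ValueError):
            make_mobilogram([GaussianComponent(5.0, 0.8, 1.0)],
                            axis=np.array([3.0, 2.0, 1.0, 0.5, 0.4, 0.3,
                                           0.2, 0.1]))


class TestMobilogramForChannel:
    def test_component_areas_match_contributions(self):
        truth = default_ground_truth()
        spec = make_spectrum(truth, noise_frac=0.0)
        ch = next(c for c in spec.channels if len(c.ions) == 4)
        mob, comps = mobilogram_for_channel(truth, ch, noise_frac=0.0)
        total = sum(c.A for c in comps)
        by_label = {}
        for c in comps:
            by_label[c.label] = by_label.get(c.label, 0.0) + c.A / total
        for label, frac in ch.contributors.items():
            assert by_label[label] == pytest.approx(frac, rel=1e-9)

    def test_spacing_anchors_only_when_resolvable(self):
        truth = default_ground_truth()
        spec = make_spectrum(truth, noise_frac=0.0)
        ch = next(c for c in spec.channels if len(c.ions) == 4)
        mob, _ = mobilogram_for_channel(truth, ch, noise_frac=0.0,
                                        resolution=10000.0)
        half_width = 0.5 * ch.mz / 10000.0
        anchored = {round(s, 6) for _, s in mob.peak_spacings}
        for _, _, z in ch.ions:
            spacing = C13_C12_DELTA / z
            assert (round(spacing, 6) in anchored) == (spacing > half_width)


class TestMakeCalibrationSet:
    def test_all_default_calibrants_present(self):
        ions = make_calibration_set(scale=450.0, exponent=0.55, c=1.41)
        assert len(ions) == 19

    def test_noise_reproducible_with_seed(self):
        a = make_calibration_set(450.0, 0.55, 1.41, noise_frac=0.01,
                                 rng=np.random.default_rng(5))
        b = make_calibration_set(450.0, 0.55, 1.41, noise_frac=0.01,
                                 rng=np.random.default_rng(5))
        assert [i.drift_time for i in a] == [i.drift_time for i in b]
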