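"""Synthetic-data generator: determinism, construction identities, scenarios."""

import numpy as np
import pytest

from emfbio.bioenergetics import correct_and_normalize, derive_metrics, normalize_to_control
from emfbio.peaks import GLASS_CENTERS, voigt_profile
from emfbio.preprocess import subtract_background
from emfbio.synthetic import (
    DEFAULT_CELL_PEAKS,
    RespirometryScenario,
    SpectrumScenario,
    SyntheticPeak,
    generate_background_spectrum,
    generate_cell_spectrum,
    generate_experiment,
    generate_respirometry_cohort,
    sample_ratio_markers,
)


class TestSpectrumScenario:
    def test_exposed_one_hour_must_be_null(self):
        with pytest.raises(ValueError, match="1 h"):
            SpectrumScenario(dna_attenuation={1.0: 0.9, 5.0: 0.8})

    def test_attenuation_must_be_nonincreasing(self):
        with pytest.raises(ValueError, match="non-increasing"):
            SpectrumScenario(dna_attenuation={1.0: 1.0, 5.0: 0.8, 12.0: 0.9})

    def test_attenuation_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            SpectrumScenario(dna_attenuation={1.0: 1.0, 5.0: 1.2})

    def test_exposed_twenty_hours_scales_dna_ratio(self):
        ctrl = SpectrumScenario(group="control")
        expo = SpectrumScenario(group="exposed", exposure_hours=20.0)
        for marker in ("I785/I1003", "I1092/I1003"):
            assert expo.true_ratio(marker) == pytest.approx(
                0.82 * ctrl.true_ratio(marker))
        # the 1578/1615 marker moves by attenuation / protein gain
        assert expo.true_ratio("I1578/I1615") == pytest.approx(
            0.82 / 1.05 * ctrl.true_ratio("I1578/I1615"))

    def test_control_and_one_hour_unaffected(self):
        ctrl = SpectrumScenario(group="control", exposure_hours=20.0)
        one_h = SpectrumScenario(group="exposed", exposure_hours=1.0)
        for marker in ("I785/I1003", "I1092/I1003", "I1578/I1615"):
            assert one_h.true_ratio(marker) == ctrl.true_ratio(marker)


class TestSpectrumGeneration:
    def test_deterministic_under_fixed_seed(self):
        scn = SpectrumScenario(seed=42)
        a = generate_cell_spectrum(scn)
        b = generate_cell_spectrum(scn)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(generate_background_spectrum(scn).intensities,
                              generate_background_spectrum(scn).intensities)

    def test_different_seeds_differ(self):
        a = generate_cell_spectrum(SpectrumScenario(seed=1))
        b = generate_cell_spectrum(SpectrumScenario(seed=2))
        assert not np.array_equal(a.intensities, b.intensities)

    def test_single_peak_noiseless_is_pure_voigt(self):
        pk = SyntheticPeak(1003.0, 0.9, 4.0, 3.0)
        scn = SpectrumScenario(peak_catalogue=(pk,), glass_peaks=(),
                               fluorescence_coeffs=(0.0,), background_coeffs=(0.0,),
                               noise_sd=0.0, cell_variability_cv=0.0)
        s = generate_cell_spectrum(scn)
        expected = voigt_profile(s.wavenumbers, pk.center, pk.sigma, pk.gamma,
                                 area=pk.area)
        assert np.allclose(s.intensities, expected, atol=1e-14)

    def test_background_contains_glass_bands(self):
        scn = SpectrumScenario(noise_sd=0.0)
        assert tuple(p.center for p in scn.glass_peaks) == GLASS_CENTERS == (893, 932, 964)
        bg = generate_background_spectrum(scn)
        for c in GLASS_CENTERS:
            i = np.argmin(np.abs(bg.wavenumbers - c))
            window = bg.intensities[max(i - 30, 0):i + 30]
            assert bg.intensities[i] > np.percentile(window, 25)

    def test_noiseless_subtraction_cancels_glass_and_substrate(self):
        scn = SpectrumScenario(noise_sd=0.0, cell_variability_cv=0.0)
        cell, truth = generate_cell_spectrum(scn, return_truth=True)
        bg = generate_background_spectrum(scn)
        sub = subtract_background(cell, bg)
        # residual = cellular peaks + fluorescence only: at glass centers the
        # glass contribution must be exactly gone
        from emfbio.synthetic import _poly_on_grid, _voigt_sum
        expected = _voigt_sum(cell.wavenumbers, scn.peak_catalogue,
                              [truth[p.center] for p in scn.peak_catalogue])
        expected += _poly_on_grid(cell.wavenumbers, scn.fluorescence_coeffs,
                                  scn.wn_min, scn.wn_max)
        assert np.allclose(sub.intensities, expected, atol=1e-12)

    def test_experiment_yields_paired_records(self):
        scn = SpectrumScenario(seed=3)
        pairs = generate_experiment(scn, 4)
        assert len(pairs) == 4
        assert all(c.meta.kind == "cell" and b.meta.kind == "background"
                   for c, b in pairs)
        ids = [c.meta.sample_id for c, _ in pairs]
        assert len(set(ids)) == 4


class TestRatioSampler:
    def test_mean_ratio_near_truth(self):
        scn = SpectrumScenario(group="exposed", exposure_hours=20.0, seed=7)
        markers = sample_ratio_markers(scn, 4000)
        vals = np.array([m.get("I785/I1003") for m in markers])
        # lognormal ratio: median equals the scenario truth
        assert np.median(vals) == pytest.approx(scn.true_ratio("I785/I1003"), rel=0.01)

    def test_deterministic_and_labelled(self):
        scn = SpectrumScenario(seed=9)
        a = sample_ratio_markers(scn, 5)
        b = sample_ratio_markers(scn, 5)
        assert [m.ratios for m in a] == [m.ratios for m in b]
        assert all(m.group == "control" for m in a)


class TestRespirometryCohort:
    def test_zero_variability_reproduces_baselines_exactly(self):
        scn = RespirometryScenario(inter_subject_cv=0.0, assay_cv=0.0)
        pairs = generate_respirometry_cohort(scn, 1)
        ctrl, _ = pairs[0]
        rates = correct_and_normalize(ctrl)
        assert rates.ocr_r == pytest.approx(scn.baseline_ocrr, rel=1e-12)
        assert rates.ocr_o == pytest.approx(scn.baseline_ocrr * scn.coupling_fraction,
                                            rel=1e-12)

    def test_rotenone_floor_is_stated_fraction_of_raw_resting(self):
        scn = RespirometryScenario(inter_subject_cv=0.0, assay_cv=0.0)
        ctrl, _ = generate_respirometry_cohort(scn, 1)[0]
        assert ctrl.ocr_rotenone == pytest.approx(
            scn.rotenone_fraction * ctrl.ocr_resting_raw, rel=1e-12)

    def test_null_scenario_exposed_equals_control(self):
        scn = RespirometryScenario(inter_subject_cv=0.0, assay_cv=0.0).null()
        for ctrl, expo in generate_respirometry_cohort(scn, 2):
            assert expo.ocr_resting_raw == pytest.approx(ctrl.ocr_resting_raw)
            assert expo.ocr_oligomycin_raw == pytest.approx(ctrl.ocr_oligomycin_raw)

    def test_programmed_shift_recovered_through_normalization(self):
        scn = RespirometryScenario(inter_subject_cv=0.0, assay_cv=0.0)
        for ctrl, expo in generate_respirometry_cohort(scn, 1):
            if ctrl.exposure_hours != 20.0:
                continue
            m_c = derive_metrics(correct_and_normalize(ctrl))
            m_e = derive_metrics(correct_and_normalize(expo))
            assert normalize_to_control(m_e, m_c, "ocr_r") == pytest.approx(1.55, rel=1e-12)

    def test_deterministic_under_seed(self):
        scn = RespirometryScenario(seed=4)
        a = generate_respirometry_cohort(scn, 2)
        b = generate_respirometry_cohort(scn, 2)
        assert all(x[0].ocr_resting_raw == y[0].ocr_resting_raw for x, y in zip(a, b))
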