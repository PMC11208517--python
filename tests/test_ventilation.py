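import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pulmovent as pv
from pulmovent.core import CTVolume, LungLabelVolume
from pulmovent.errors import CalibrationError
from pulmovent.ventilation import (CLASS_FIBROSIS, CLASS_LOW, CLASS_MIXED,
                                   CLASS_NORMAL, VentilationThresholds,
                                   calibrate_thresholds, classify_values,
                                   classify_voxels, delta_svg,
                                   specific_gas_volume)

from oracles import classify_oracle

TISSUE_SV = 1.0 / 1.065


def _svg_of(hu):
    ct = CTVolume(np.full((4, 4, 4), float(hu)), [0.05] * 3)
    m = np.ones((4, 4, 4), dtype=bool)
    return specific_gas_volume(ct, m).values[0, 0, 0]


class TestSpecificGasVolume:
    def test_closed_form_minus_500(self):
        # 1000/500 - 1/1.065
        assert _svg_of(-500) == pytest.approx(1000 / 500 - TISSUE_SV, abs=1e-12)
        assert _svg_of(-500) == pytest.approx(1.061, abs=1e-3)

    def test_zero_crossing_near_65_hu(self):
        # solving 1000/(HU+1000) = 1/1.065 gives HU = 65 exactly
        assert _svg_of(65.0) == pytest.approx(0.0, abs=1e-12)
        assert _svg_of(64.0) > 0 > _svg_of(66.0)

    def test_strictly_decreasing_in_hu(self):
        hus = np.linspace(-990, 1000, 200)
        svgs = np.array([_svg_of(h) for h in hus])
        assert (np.diff(svgs) < 0).all()

    def test_clipping_bounds_svg(self):
        assert _svg_of(-1000) == pytest.approx(1000 / 10 - TISSUE_SV)

    def test_nan_outside_mask(self):
        ct = CTVolume(np.full((4, 4, 4), -500.0), [0.05] * 3)
        m = np.zeros((4, 4, 4), dtype=bool)
        m[0, 0, 0] = True
        out = specific_gas_volume(ct, m)
        assert np.isnan(out.values[1, 1, 1])
        assert np.isfinite(out.values[0, 0, 0])

    @settings(max_examples=30, deadline=None)
    @given(hu=st.floats(-990, 990), tissue_sv=st.floats(0.5, 1.2))
    def test_formula_property(self, hu, tissue_sv):
        ct = CTVolume(np.full((2, 2, 2), hu), [1] * 3)
        out = specific_gas_volume(ct, np.ones((2, 2, 2), bool),
                                  tissue_sv=tissue_sv)
        assert out.values[0, 0, 0] == pytest.approx(
            1000.0 / (hu + 1000.0) - tissue_sv, rel=1e-12)


class TestDeltaSVg:
    def test_identical_maps_give_zero(self):
        ct = CTVolume(np.full((4, 4, 4), -400.0), [1] * 3)
        m = np.ones((4, 4, 4), bool)
        s = specific_gas_volume(ct, m)
        d = delta_svg(s, s)
        assert (d.values[d.mask] == 0).all()

    def test_mask_intersection(self):
        ct = CTVolume(np.full((4, 4, 4), -400.0), [1] * 3)
        m1 = np.zeros((4, 4, 4), bool)
        m2 = np.zeros((4, 4, 4), bool)
        m1[:2] = True
        m2[1:3] = True
        d = delta_svg(specific_gas_volume(ct, m1), specific_gas_volume(ct, m2))
        assert (d.mask == (m1 & m2)).all()

    def test_lesions_have_small_delta_parenchyma_positive(self, lesion_pair64,
                                                          thresholds64, config):
        from pulmovent.registration import register_pair, warp_volume
        from pulmovent.ventilation import svg_arrays_for_pair

        p01, p02, truth = lesion_pair64
        field = register_pair(p01, p02)
        warped = warp_volume(p02, field)
        wmask = warp_volume(truth.mask_p02, field)
        _, _, delta = svg_arrays_for_pair(p01, warped, truth.mask.labels > 0,
                                          wmask.labels > 0,
                                          config.tissue_specific_volume)
        lesion = truth.lesion_labels & delta.mask
        parench = (truth.mask.labels > 0) & ~truth.lesion_labels & delta.mask
        assert np.median(np.abs(delta.values[lesion])) < thresholds64.beta
        assert np.median(delta.values[parench]) > thresholds64.beta

    def test_amplitude_sweep_increases_mean_delta(self):
        from pulmovent.registration import warp_volume
        from pulmovent.ventilation import svg_arrays_for_pair

        means = []
        for amp in (0.04, 0.08, 0.12):
            spec = pv.PhantomSpec(grid_shape=(48, 48, 48), rng_seed=21,
                                  noise_sd_hu=0.0)
            p01, p02, truth = pv.make_phantom_pair(
                spec, model=pv.DeformationModel(amplitude_mm=amp))
            warped = warp_volume(p02, truth.displacement)
            wmask = warp_volume(truth.mask_p02, truth.displacement)
            _, _, delta = svg_arrays_for_pair(
                p01, warped, truth.mask.labels > 0, wmask.labels > 0)
            means.append(np.nanmean(delta.values[delta.mask]))
        assert means[0] < means[1] < means[2]


class TestCalibration:
    def _fake_pair(self, rng, n=1000, shift=0.0):
        s1 = rng.normal(1.2 + shift, 0.2, n)
        s2 = rng.normal(0.9 + shift, 0.2, n)
        return s1, s2, s1 - s2

    def test_single_animal_equals_own_percentiles(self):
        rng = np.random.default_rng(0)
        pair = self._fake_pair(rng)
        thr = calibrate_thresholds([pair])
        assert thr.alpha_I == pytest.approx(np.percentile(pair[0], 5))
        assert thr.alpha_E == pytest.approx(np.percentile(pair[1], 5))
        assert thr.beta == pytest.approx(np.percentile(pair[2], 25))

    def test_identical_animals_equal_common_percentiles(self):
        rng = np.random.default_rng(1)
        pair = self._fake_pair(rng)
        thr = calibrate_thresholds([pair, pair, pair])
        assert thr.alpha_I == pytest.approx(np.percentile(pair[0], 5))

    def test_pooled_mode_differs_from_per_animal(self):
        rng = np.random.default_rng(2)
        pairs = [self._fake_pair(rng, shift=s) for s in (0.0, 0.5)]
        per = calibrate_thresholds(pairs, mode="per_animal")
        pooled = calibrate_thresholds(pairs, mode="pooled")
        assert per.alpha_I != pooled.alpha_I

    def test_empty_cohort_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_thresholds([])

    def test_missing_delta_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_thresholds([(np.ones(10), np.ones(10), np.array([]))])

    def test_non_compressive_cohort_warns(self):
        rng = np.random.default_rng(3)
        s1 = rng.normal(1.0, 0.1, 500)
        with pytest.warns(UserWarning, match="beta"):
            calibrate_thresholds([(s1, s1 + 1.0, s1 - (s1 + 1.0))])


class TestClassification:
    THR = VentilationThresholds(alpha_I=1.0, alpha_E=0.8, beta=0.1)

    def test_delta_exactly_beta_is_normal(self):
        codes = classify_values(np.array([0.5]), np.array([0.5]),
                                np.array([0.1]), self.THR)
        assert codes[0] == CLASS_NORMAL

    def test_all_three_conditions_give_fibrosis(self):
        codes = classify_values(np.array([0.5]), np.array([0.5]),
                                np.array([0.0]), self.THR)
        assert codes[0] == CLASS_FIBROSIS

    def test_mixed_case_routes_to_low_by_default(self):
        # only the inspiratory condition holds
        codes = classify_values(np.array([0.5]), np.array([0.9]),
                                np.array([0.0]), self.THR)
        assert codes[0] == CLASS_LOW

    def test_mixed_case_separate_class_option(self):
        codes = classify_values(np.array([0.5]), np.array([0.9]),
                                np.array([0.0]), self.THR,
                                mixed_class="separate")
        assert codes[0] == CLASS_MIXED

    def test_vacuous_beta_gives_all_normal(self, basal_reports64):
        rep = basal_reports64[0]
        thr = VentilationThresholds(alpha_I=1.0, alpha_E=0.8, beta=-1e9)
        codes = classify_values(rep.arrays["svg1"], rep.arrays["svg2"],
                                rep.arrays["delta"], thr)
        assert (codes == CLASS_NORMAL).all()

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10 ** 6))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        s1 = rng.normal(1.0, 0.5, n)
        s2 = rng.normal(0.8, 0.5, n)
        d = rng.normal(0.1, 0.2, n)
        got = classify_values(s1, s2, d, self.THR)
        want = classify_oracle(s1, s2, d, 1.0, 0.8, 0.1)
        assert list(got) == want

    def test_partition_exact(self, basal_reports64, thresholds64):
        rep = basal_reports64[1]
        codes = classify_values(rep.arrays["svg1"], rep.arrays["svg2"],
                                rep.arrays["delta"], thresholds64)
        n = codes.size
        counts = [(codes == c).sum() for c in
                  (CLASS_NORMAL, CLASS_LOW, CLASS_FIBROSIS)]
        assert sum(counts) == n

    def test_classify_voxels_regions_sum_to_100(self, lesion_pair64,
                                                thresholds64, config):
        from pulmovent.registration import register_pair, warp_volume
        from pulmovent.ventilation import svg_arrays_for_pair

        p01, p02, truth = lesion_pair64
        field = register_pair(p01, p02)
        warped = warp_volume(p02, field)
        wmask = warp_volume(truth.mask_p02, field)
        svg1, svg2, delta = svg_arrays_for_pair(
            p01, warped, truth.mask.labels > 0, wmask.labels > 0)
        report = classify_voxels(svg1, svg2, delta, thresholds64, truth.mask)
        for region, pct in report.percentages.items():
            assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_uncalibrated_thresholds_rejected(self):
        ct = CTVolume(np.full((4, 4, 4), -500.0), [1] * 3)
        m = np.ones((4, 4, 4), bool)
        s = specific_gas_volume(ct, m)
        with pytest.raises(CalibrationError):
            classify_voxels(s, s, delta_svg(s, s), None)


class TestCalibrationSelfConsistency:
    def test_fraction_below_alpha_i_near_5pct(self, basal_reports64,
                                              thresholds64):
        fracs = [100.0 * np.mean(r.arrays["svg1"] < thresholds64.alpha_I)
                 for r in basal_reports64]
        assert np.mean(fracs) == pytest.approx(5.0, abs=3.0)

    def test_fraction_below_beta_near_25pct(self, basal_reports64,
                                            thresholds64):
        fracs = [100.0 * np.mean(r.arrays["delta"] < thresholds64.beta)
                 for r in basal_reports64]
        assert np.mean(fracs) == pytest.approx(25.0, abs=5.0)

    def test_mean_normal_vent_near_75pct(self, basal_reports64, thresholds64):
        pcts = []
        for rep in basal_reports64:
            codes = classify_values(rep.arrays["svg1"], rep.arrays["svg2"],
                                    rep.arrays["delta"], thresholds64)
            pcts.append(100.0 * np.mean(codes == CLASS_NORMAL))
        assert np.mean(pcts) == pytest.approx(75.0, abs=5.0)


def test_fibrosis_monotone_in_lesion_fraction(thresholds64, config):
    from pulmovent.registration import register_pair, warp_volume
    from pulmovent.ventilation import svg_arrays_for_pair

    fractions, fib = [], []
    for count in (0, 2, 4):
        spec = pv.PhantomSpec(grid_shape=(48, 48, 48), rng_seed=33)
        lesions = pv.LesionSpec(count=count) if count else None
        p01, p02, truth = pv.make_phantom_pair(spec, lesions=lesions)
        field = register_pair(p01, p02)
        warped = warp_volume(p02, field)
        wmask = warp_volume(truth.mask_p02, field)
        svg1, svg2, delta = svg_arrays_for_pair(
            p01, warped, truth.mask.labels > 0, wmask.labels > 0)
        report = classify_voxels(svg1, svg2, delta, thresholds64, truth.mask)
        fractions.append(truth.lesion_labels.sum() / (truth.mask.labels > 0).sum())
        fib.append(report.percentages["whole"]["fibrosis"])
    assert fractions == sorted(fractions)
    assert fib == sorted(fib)
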