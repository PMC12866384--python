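import numpy as np
import pytest

import pyp_dynaquant as pq


def _img(values_per_frame, frames, voxel=4.92, shape=(4, 4, 4)):
    data = np.stack([np.full(shape, v, float) for v in values_per_frame],
                    axis=-1)
    return pq.DynamicImage(data, voxel, pq.FrameSchedule(tuple(frames)))


class TestExtractTac:
    def test_flat_phantom_gives_flat_tac(self):
        img = _img([7.0, 7.0, 7.0], [(0, 5), (5, 5), (10, 5)])
        dose = pq.DoseRecord(injected_activity_Bq=1e9, reference_time_min=0.0)
        mask = np.ones((4, 4, 4), bool)
        tac = pq.extract_tac(img, {"m": mask}, dose, 70.0)["m"]
        assert np.allclose(tac.suv_mean, tac.suv_mean[0])
        assert np.allclose(tac.suv_max, tac.suv_mean)

    def test_noiseless_attr_myocardial_tac_passes_through_anchors(
            self, noiseless_attr_subject):
        subject = noiseless_attr_subject
        dose = pq.net_injected_activity(subject.record)
        image = pq.decay_correct_image(subject.images["10-65min"],
                                       dose.reference_time_min)
        masks = {"LV_myo": subject.geometry.labels["LV_myo"]}
        tac = pq.extract_tac(image, masks, dose,
                             subject.record.weight_kg)["LV_myo"]
        curve = pq.make_tissue_tac(pq.default_kinetics("ATTR")["LV_myo"])
        for t, v in zip(tac.times_min, tac.suv_mean):
            assert v == pytest.approx(float(curve(t)), rel=5e-3)

    def test_single_frame_tac_equals_static_stats(self):
        img = _img([3.0], [(90, 15)])
        dose = pq.DoseRecord(injected_activity_Bq=1e9, reference_time_min=0.0)
        mask = np.ones((4, 4, 4), bool)
        tac = pq.extract_tac(img, {"m": mask}, dose, 70.0)["m"]
        stats = pq.voi_statistics(img, mask)
        assert len(tac.times_min) == 1
        assert tac.suv_mean[0] == pytest.approx(
            pq.suv(stats.mean, dose, 70.0))

    def test_requires_concentration_units(self):
        img = _img([1.0], [(0, 1)])
        img.units = "counts/voxel/s"
        dose = pq.DoseRecord(injected_activity_Bq=1e9, reference_time_min=0.0)
        with pytest.raises(pq.DegenerateInputError):
            pq.extract_tac(img, {"m": np.ones((4, 4, 4), bool)}, dose, 70.0)


class TestSynthesizeStatic:
    def test_duration_weighted_mean(self):
        img = _img([2.0, 4.0], [(0, 5), (5, 10)])
        static = pq.synthesize_static(img, 0.0, 15.0)
        assert np.allclose(static.frame(0), (2 * 5 + 4 * 10) / 15.0)

    def test_identical_frames_unchanged(self):
        img = _img([3.5, 3.5, 3.5], [(0, 5), (5, 5), (10, 5)])
        static = pq.synthesize_static(img, 0.0, 15.0)
        assert np.allclose(static.frame(0), 3.5)

    def test_window_matching_one_frame(self):
        img = _img([2.0, 9.0], [(0, 5), (5, 5)])
        static = pq.synthesize_static(img, 5.0, 10.0)
        assert np.allclose(static.frame(0), 9.0)

    def test_partial_overlap_weighting_is_framing_invariant(self):
        # same piecewise-constant signal framed two ways -> same window mean
        coarse = _img([2.0, 6.0], [(0, 10), (10, 10)])
        fine = _img([2.0, 2.0, 6.0, 6.0], [(0, 5), (5, 5), (10, 5), (15, 5)])
        a = pq.synthesize_static(coarse, 5.0, 15.0).frame(0)
        b = pq.synthesize_static(fine, 5.0, 15.0).frame(0)
        assert np.allclose(a, b)

    def test_linearity_in_image(self):
        rng = np.random.default_rng(0)
        data = rng.random((4, 4, 4, 3))
        frames = [(0, 5), (5, 5), (10, 5)]
        sched = pq.FrameSchedule(tuple(frames))
        img1 = pq.DynamicImage(data, 4.92, sched)
        img2 = pq.DynamicImage(2.5 * data, 4.92, sched)
        a = pq.synthesize_static(img1, 2.0, 12.0).frame(0)
        b = pq.synthesize_static(img2, 2.0, 12.0).frame(0)
        assert np.allclose(b, 2.5 * a)

    def test_empty_overlap_rejected(self):
        img = _img([1.0], [(0, 5)])
        with pytest.raises(pq.WindowError):
            pq.synthesize_static(img, 30.0, 45.0)

    def test_window_recorded_as_provenance(self):
        img = _img([1.0, 2.0], [(10, 5), (15, 5)])
        static = pq.synthesize_static(img, 10.0, 20.0)
        assert static.schedule.frames == ((10.0, 10.0),)
        assert static.meta["synthetic_static_window"] == [10.0, 20.0]


class TestBloodPoolSubtract:
    def _early(self, value=4.0, shape=(6, 6, 6)):
        frames = [(i * 0.25, 0.25) for i in range(20)]
        data = np.full(shape + (20,), value)
        return pq.DynamicImage(data, 4.92, pq.FrameSchedule(tuple(frames)))

    def test_proportional_target_cancels_exactly(self):
        early = self._early(4.0)
        target = pq.DynamicImage(np.full((6, 6, 6), 8.0), 4.92,
                                 pq.FrameSchedule(((10.0, 15.0),)))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        out = pq.blood_pool_subtract(target, early, mask)
        assert np.allclose(out.frame(0), 0.0)
        assert out.meta["subtraction_scale"] == pytest.approx(2.0)

    def test_additive_myocardial_signal_recovered_exactly(self):
        early = self._early(4.0)
        bp_mask = np.zeros((6, 6, 6), bool)
        bp_mask[0:2, 0:2, 0:2] = True
        myo_signal = np.zeros((6, 6, 6))
        myo_signal[4:6, 4:6, 4:6] = 3.7   # disjoint from the blood-pool VOI
        target = pq.DynamicImage(1.5 * 4.0 + myo_signal, 4.92,
                                 pq.FrameSchedule(((10.0, 15.0),)))
        out = pq.blood_pool_subtract(target, early, bp_mask)
        assert np.allclose(out.frame(0), myo_signal, atol=1e-12)

    def test_negative_residuals_clamped_to_zero(self):
        early = self._early(4.0)
        target = pq.DynamicImage(np.full((6, 6, 6), 1.0), 4.92,
                                 pq.FrameSchedule(((10.0, 15.0),)))
        mask = np.ones((6, 6, 6), bool)
        out = pq.blood_pool_subtract(target, early, mask, scale=10.0)
        assert out.frame(0).min() == 0.0

    def test_zero_template_blood_pool_rejected(self):
        early = self._early(0.0)
        target = pq.DynamicImage(np.ones((6, 6, 6)), 4.92,
                                 pq.FrameSchedule(((10.0, 15.0),)))
        with pytest.raises(pq.DegenerateInputError):
            pq.blood_pool_subtract(target, early, np.ones((6, 6, 6), bool))

    @pytest.mark.parametrize("fixture_name, bound, comparison", [
        ("noiseless_non_attr_subject", 0.10, "lt"),
        ("noiseless_attr_subject", 0.50, "gt"),
    ])
    def test_subtraction_contrast_between_groups(self, request, fixture_name,
                                                 bound, comparison):
        """Early myocardial signal is blood-pool-driven in non-ATTR subjects
        (subtraction removes >90% of it) but persists in ATTR subjects
        (>50% survives)."""
        subject = request.getfixturevalue(fixture_name)
        labels = subject.geometry.labels
        target = pq.synthesize_static(subject.images["10-65min"], 10.0, 25.0)
        out = pq.blood_pool_subtract(target, subject.images["0-5min"],
                                     labels["LA_bp"])
        before = pq.voi_statistics(target, labels["LV_myo"]).mean
        after = pq.voi_statistics(out, labels["LV_myo"]).mean
        ratio = after / before
        if comparison == "lt":
            assert ratio < bound
        else:
            assert ratio > bound
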