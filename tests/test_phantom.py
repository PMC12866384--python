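import numpy as np
import pytest
from scipy import ndimage

import pyp_dynaquant as pq
from pyp_dynaquant.phantom import ConfigurationError, LABEL_TO_KINETICS

TISSUES = ("LV_myo", "LV_bp", "LA_bp", "LS")


class TestGeometry:
    def test_masks_disjoint_inside_body_and_large_enough(self, geometry48):
        occupied = np.zeros(geometry48.grid_shape, bool)
        body = geometry48.labels["body"]
        for name in TISSUES:
            mask = geometry48.labels[name]
            assert not (mask & occupied).any(), f"{name} overlaps"
            assert not (mask & body).any(), f"{name} overlaps soft tissue"
            assert mask.sum() >= 30, f"{name} too small"
            occupied |= mask

    def test_lv_blood_pool_enclosed_by_myocardial_shell_in_plane(self, geometry48):
        myo = geometry48.labels["LV_myo"]
        bp = geometry48.labels["LV_bp"]
        for z in range(geometry48.grid_shape[2]):
            if not bp[:, :, z].any():
                continue
            filled = ndimage.binary_fill_holes(myo[:, :, z])
            assert (bp[:, :, z] <= filled).all(), f"open shell at slice {z}"

    @pytest.mark.parametrize("shape", [(48, 48, 48), (96, 96, 96)])
    def test_voxelized_volumes_match_analytic_shapes(self, shape):
        geom = pq.build_phantom_geometry(shape, 4.92)
        analytic = pq.analytic_region_volumes_ml()
        for name, expected in analytic.items():
            measured = geom.region_volume_ml(name)
            assert abs(measured - expected) / expected < 0.15, name

    def test_too_small_grid_names_offending_region(self):
        with pytest.raises(pq.PhantomSizingError, match="region"):
            pq.build_phantom_geometry((16, 16, 16), 4.92)

    def test_deterministic(self):
        a = pq.build_phantom_geometry((48, 48, 48), 4.92)
        b = pq.build_phantom_geometry((48, 48, 48), 4.92)
        for name in a.labels:
            assert np.array_equal(a.labels[name], b.labels[name])


class TestTissueKinetics:
    def test_curve_passes_through_every_anchor(self):
        for group in ("ATTR", "non-ATTR"):
            for kin in pq.default_kinetics(group).values():
                tac = pq.make_tissue_tac(kin)
                for t, v in kin.anchors:
                    assert tac(t) == pytest.approx(v, rel=1e-12)

    def test_attr_myocardium_10min_window_anchor(self):
        tac = pq.make_tissue_tac(pq.default_kinetics("ATTR")["LV_myo"])
        assert tac(17.5) == pytest.approx(3.86)

    @pytest.mark.parametrize("group", ["ATTR", "non-ATTR"])
    def test_bone_peaks_at_90min(self, group):
        tac = pq.make_tissue_tac(pq.default_kinetics(group)["LS"])
        t = np.linspace(0.0, 90.0, 361)
        assert np.all(tac(97.5) >= tac(t))

    def test_no_overshoot_between_adjacent_anchors(self):
        # shape preservation: between consecutive anchors the curve stays
        # within the anchor values' range
        for group in ("ATTR", "non-ATTR"):
            for kin in pq.default_kinetics(group).values():
                tac = pq.make_tissue_tac(kin)
                for (t0, v0), (t1, v1) in zip(kin.anchors, kin.anchors[1:]):
                    t = np.linspace(t0, t1, 101)
                    v = tac(t)
                    lo, hi = min(v0, v1), max(v0, v1)
                    assert np.all(v >= lo - 1e-12) and np.all(v <= hi + 1e-12)

    def test_constant_pair_gives_constant_curve(self):
        kin = pq.TissueKinetics("x", ((0.0, 1.0), (10.0, 1.0)))
        tac = pq.make_tissue_tac(kin)
        assert np.allclose(tac(np.linspace(0, 10, 50)), 1.0)

    def test_constant_extrapolation_beyond_last_anchor(self):
        kin = pq.TissueKinetics("x", ((5.0, 2.0), (10.0, 4.0)))
        tac = pq.make_tissue_tac(kin)
        assert tac(200.0) == pytest.approx(4.0)
        assert tac(0.0) == pytest.approx(2.0)

    def test_nonnegative_on_study_span(self):
        for group in ("ATTR", "non-ATTR"):
            for kin in pq.default_kinetics(group).values():
                tac = pq.make_tissue_tac(kin)
                assert np.all(tac(np.linspace(0, 160, 641)) >= 0)

    @pytest.mark.parametrize("anchors", [
        ((0.0, 1.0),),                      # too few
        ((0.0, 1.0), (0.0, 2.0)),           # non-increasing times
        ((0.0, 0.0), (1.0, 1.0)),           # non-positive SUV
    ])
    def test_invalid_kinetics_rejected(self, anchors):
        with pytest.raises(ConfigurationError):
            pq.TissueKinetics("x", anchors)


class TestSubjectGeneration:
    def test_filling_round_trip_recovers_curve(self, noiseless_attr_subject):
        """With blur/noise/variability off, VOI SUVmean at each frame midpoint
        equals the kinetics curve to within 0.1%."""
        subject = noiseless_attr_subject
        dose = pq.net_injected_activity(subject.record)
        kin = pq.default_kinetics("ATTR")
        for key, image in subject.images.items():
            corrected = pq.decay_correct_image(image, dose.reference_time_min)
            for label in ("LV_myo", "LA_bp", "LV_bp", "LS"):
                tac = pq.make_tissue_tac(kin[LABEL_TO_KINETICS[label]])
                for j, t in enumerate(image.schedule.midpoints):
                    stats = pq.voi_statistics(corrected,
                                              subject.geometry.labels[label],
                                              frame=j)
                    measured = pq.suv(stats.mean, dose, subject.record.weight_kg)
                    assert measured == pytest.approx(float(tac(t)), rel=1e-3)

    def test_attr_ordering_myo_at_least_bp_from_10min(self, small_noisy_cohort):
        for subject in small_noisy_cohort:
            if subject.group != "ATTR":
                continue
            kin = pq.default_kinetics("ATTR")
            myo = pq.make_tissue_tac(kin["LV_myo"])
            bp = pq.make_tissue_tac(kin["bp"])
            sched = pq.default_frame_schedule()
            late = sched.starts >= 10.0
            t = sched.midpoints[late]
            assert np.all(myo(t) * subject.multipliers["LV_myo"]
                          >= bp(t) * subject.multipliers["bp"])

    def test_non_attr_ordering_bp_above_myo_everywhere(self, small_noisy_cohort):
        for subject in small_noisy_cohort:
            if subject.group != "non-ATTR":
                continue
            kin = pq.default_kinetics("non-ATTR")
            myo = pq.make_tissue_tac(kin["LV_myo"])
            bp = pq.make_tissue_tac(kin["bp"])
            t = pq.default_frame_schedule().midpoints
            assert np.all(bp(t) * subject.multipliers["bp"]
                          > myo(t) * subject.multipliers["LV_myo"])

    def test_missing_tissue_kinetics_raises(self, geometry48):
        kin = pq.default_kinetics("ATTR")
        del kin["LS"]
        with pytest.raises(ConfigurationError, match="LS"):
            pq.generate_subject("ATTR", geometry48, kin,
                                pq.NOISELESS_ACQUISITION,
                                pq.default_dose_params("ATTR"), seed=0)

    def test_poisson_noise_consistent_with_counting_statistics(self):
        """Relative SD of the VOI-mean count rate across repeated frames of a
        constant-activity phantom matches 1/sqrt(total VOI counts) within a
        factor of 1.5."""
        acq = pq.AcquisitionModel(sensitivity_cps_per_Bq_per_mL_per_voxel=2e-5,
                                  noise=True)
        means = []
        mask = None
        for seed in range(200):
            img, mask = pq.simulate_uniform_cylinder(
                20.0, 1500.0, grid_shape=(32, 32, 32), acquisition=acq,
                duration_min=1.0, seed=seed)
            means.append(img.frame(0)[mask].mean())
        concentration = 20e6 / 1500.0
        counts_per_voxel = concentration * 2e-5 * 60.0
        total_counts = counts_per_voxel * mask.sum()
        expected_rel_sd = 1.0 / np.sqrt(total_counts)
        rel_sd = np.std(means, ddof=1) / np.mean(means)
        assert rel_sd < 1.5 * expected_rel_sd
        assert rel_sd > expected_rel_sd / 1.5


class TestCohort:
    def test_group_sizes_and_labels(self, small_noisy_cohort):
        assert len(small_noisy_cohort) == 5
        assert sum(s.group == "ATTR" for s in small_noisy_cohort) == 2

    def test_no_attr_cohort(self, geometry48):
        cfg = pq.CohortConfig(grid_shape=(48, 48, 48))
        cohort = pq.generate_cohort(0, 3, cfg, seed=5)
        assert len(cohort) == 3
        assert all(s.group == "non-ATTR" for s in cohort)

    def test_same_seed_bit_identical(self):
        cfg = pq.CohortConfig(grid_shape=(48, 48, 48))
        a = pq.generate_cohort(1, 1, cfg, seed=3)
        b = pq.generate_cohort(1, 1, cfg, seed=3)
        for sa, sb in zip(a, b):
            assert sa.record == sb.record
            assert sa.multipliers == sb.multipliers
            for key in sa.images:
                assert np.array_equal(sa.images[key].data, sb.images[key].data)

    def test_negative_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            pq.generate_cohort(-1, 2, None, seed=0)
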