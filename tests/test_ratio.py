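import numpy as np
import pytest

from plexdyn.phantom import PhantomSpec, make_phantom
from plexdyn.ratio import (CalibrationParams, calibrate_intensities,
                           calibration_peaks, compute_ratio, correct_bias,
                           erode_one_voxel, histogram_peak,
                           t1t2_ratio_workflow)


def _expected_chp_ratio(spec: PhantomSpec) -> float:
    """Closed-form oracle: map the generating class means through the
    piecewise-linear anchor calibration and take the quotient."""
    def cal(value, means, order):
        xs = [means[c] for c in order]
        ys = [0.2, 0.6, 1.0]
        return np.interp(value, xs, ys)

    t1 = cal(spec.tissue_means_t1["chp"], spec.tissue_means_t1,
             ("csf", "bone", "soft_tissue"))
    t2 = cal(spec.tissue_means_t2["chp"], spec.tissue_means_t2,
             ("bone", "soft_tissue", "csf"))
    return t1 / t2


class TestCorrectBias:
    def test_bias_free_volume_is_identity(self):
        p = make_phantom(PhantomSpec(seed=4, noise_sd=0.0, bias_amplitude=0.0))
        soft = p.ref_masks["soft_tissue"]
        out = correct_bias(p.t1w, soft)
        rel = np.abs(out[soft] - p.t1w[soft]) / p.t1w[soft]
        assert rel.max() < 1e-6

    def test_known_degree2_bias_removed(self):
        spec = PhantomSpec(seed=4, noise_sd=0.0, bias_amplitude=0.1)
        p = make_phantom(spec)
        soft = p.ref_masks["soft_tissue"]
        out = correct_bias(p.t1w, soft)
        ratio = out[soft] / spec.tissue_means_t1["soft_tissue"]
        assert ratio.std() / ratio.mean() < 0.01

    def test_errors(self):
        vol = np.ones((8, 8, 8))
        with pytest.raises(ValueError, match="empty"):
            correct_bias(vol, np.zeros_like(vol, dtype=bool))
        vol[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="positive"):
            correct_bias(vol, np.ones_like(vol, dtype=bool))


class TestHistogramPeak:
    def test_unimodal_mode(self, rng):
        values = rng.normal(100, 5, 5000)
        assert histogram_peak(values, 1.25) == pytest.approx(100, abs=0.5)

    def test_bimodal_dominant_mode(self, rng):
        values = np.concatenate([rng.normal(50, 2, 1000),
                                 rng.normal(120, 2, 4000)])
        assert histogram_peak(values, 1.0) == pytest.approx(120, abs=1.0)

    def test_constant_and_too_few(self):
        assert histogram_peak(np.full(60, 7.5), 1.0) == 7.5
        with pytest.raises(ValueError, match="50"):
            histogram_peak(np.arange(10.0), 1.0)


class TestCalibration:
    def test_peaks_equal_targets_gives_identity(self, rng):
        params = CalibrationParams.for_t2w()
        shape = (12, 12, 12)
        vol = rng.uniform(0.2, 1.0, shape)
        # carve disjoint slabs whose values concentrate at each anchor
        refs = {}
        refs["bone"] = np.zeros(shape, bool)
        refs["bone"][:4] = True
        vol[:4] = 0.2 + rng.normal(0, 1e-4, vol[:4].shape)
        refs["soft_tissue"] = np.zeros(shape, bool)
        refs["soft_tissue"][4:8] = True
        vol[4:8] = 0.6 + rng.normal(0, 1e-4, vol[4:8].shape)
        refs["csf"] = np.zeros(shape, bool)
        refs["csf"][8:] = True
        vol[8:] = 1.0 + rng.normal(0, 1e-4, vol[8:].shape)
        out = calibrate_intensities(vol, refs, params)
        assert np.max(np.abs(out - vol)) < 1e-3

    def test_scale_invariance(self, default_phantom):
        p = default_phantom
        params = CalibrationParams.for_t1w()
        a = calibrate_intensities(p.t1w, p.ref_masks, params)
        b = calibrate_intensities(3.0 * p.t1w, p.ref_masks, params)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_non_monotone_peaks_error(self, default_phantom):
        p = default_phantom
        params = CalibrationParams.for_t2w()  # wrong order for a T1w volume
        with pytest.raises(ValueError, match="not separable"):
            calibrate_intensities(p.t1w, p.ref_masks, params)


class TestErosion:
    def test_cube_erodes_to_center(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[1:4, 1:4, 1:4] = True
        out = erode_one_voxel(mask)
        assert out.sum() == 1 and out[2, 2, 2]

    def test_single_voxel_and_plane_vanish(self):
        single = np.zeros((5, 5, 5), dtype=bool)
        single[2, 2, 2] = True
        assert erode_one_voxel(single).sum() == 0
        plane = np.zeros((5, 5, 5), dtype=bool)
        plane[:, :, 2] = True
        assert erode_one_voxel(plane).sum() == 0


class TestComputeRatio:
    def test_constant_factor_ratio(self):
        t2 = np.full((6, 6, 6), 0.5)
        t1 = 2.0 * t2
        mask = np.zeros(t2.shape, dtype=bool)
        mask[1:5, 1:5, 1:5] = True
        res = compute_ratio(t1, t2, mask)
        assert res.mean_ratio == pytest.approx(2.0)

    def test_empty_mask_errors(self):
        vol = np.ones((4, 4, 4))
        with pytest.raises(ValueError, match="empty"):
            compute_ratio(vol, vol, np.zeros_like(vol, dtype=bool))

    def test_noisefree_phantom_recovers_class_mean_ratio(self):
        spec = PhantomSpec(seed=4, noise_sd=0.0, bias_amplitude=0.05)
        p = make_phantom(spec)
        res = t1t2_ratio_workflow(p.t1w, p.t2w, p.chp_truth_mask, p.ref_masks)
        expected = _expected_chp_ratio(spec)
        assert res.mean_ratio == pytest.approx(expected, rel=0.02)

    def test_end_to_end_invariance_to_independent_rescaling(self,
                                                            default_phantom):
        p = default_phantom
        a = t1t2_ratio_workflow(p.t1w, p.t2w, p.chp_truth_mask, p.ref_masks)
        b = t1t2_ratio_workflow(3.7 * p.t1w, 0.4 * p.t2w, p.chp_truth_mask,
                                p.ref_masks)
        assert b.mean_ratio == pytest.approx(a.mean_ratio, rel=1e-6)

    def test_erosion_reduces_partial_volume_bias(self):
        """Corrupt the boundary voxels of the ChP mask; the eroded-mask mean
        must sit closer to the true ratio than the un-eroded mean."""
        spec = PhantomSpec(seed=4, noise_sd=0.0, bias_amplitude=0.0)
        p = make_phantom(spec)
        t1 = np.full(p.t1w.shape, 2.0)
        t2 = np.ones_like(t1)  # true ratio 2 everywhere
        boundary = p.chp_truth_mask & ~erode_one_voxel(p.chp_truth_mask)
        t1[boundary] = 0.5  # partial-volume corruption on the rim
        res = compute_ratio(t1, t2, p.chp_truth_mask)
        uneroded_mean = float(np.nanmean((t1 / t2)[p.chp_truth_mask]))
        assert abs(res.mean_ratio - 2.0) < abs(uneroded_mean - 2.0)

    def test_bias_correction_commutes_when_bias_free(self):
        p = make_phantom(PhantomSpec(seed=4, noise_sd=0.0, bias_amplitude=0.0))
        with_corr = t1t2_ratio_workflow(p.t1w, p.t2w, p.chp_truth_mask,
                                        p.ref_masks, bias_correct=True)
        without = t1t2_ratio_workflow(p.t1w, p.t2w, p.chp_truth_mask,
                                      p.ref_masks, bias_correct=False)
        assert with_corr.mean_ratio == pytest.approx(without.mean_ratio,
                                                     rel=1e-6)


def test_detected_peaks_track_class_means(default_phantom):
    p = default_phantom
    peaks = calibration_peaks(p.t1w, p.ref_masks, CalibrationParams.for_t1w())
    means = p.spec.tissue_means_t1
    for cls in ("csf", "bone", "soft_tissue"):
        assert peaks[cls] == pytest.approx(means[cls], rel=0.08)
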