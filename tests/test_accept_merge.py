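import numpy as np
import pytest

import synaptodetect as sd
from synaptodetect.pipeline import (
    RULE_ROUNDNESS,
    RULE_SIZE,
    RULE_SLICE3,
    RULE_SLICE7,
    RULE_SNR_NULL,
    apply_acceptance_rules,
    filter_by_zspan,
    merge_across_planes,
    slice_average_snrs,
    snr_null_threshold,
)
from synaptodetect.detect import build_exclusion_mask


def _fit(template, snr1=2.0, snr3=2.0, snr7=1.0, z=2, y=40, x=40):
    return sd.TemplateFit(sd.CandidatePeak(z, y, x, snr1), template, snr1, snr3, snr7)


def _detection(z, voxels, template=None, family=None):
    """A hand-built accepted detection with the given footprint."""
    fp = frozenset(voxels)
    t = template or (family[0] if family else None)
    fit = sd.TemplateFit(sd.CandidatePeak(z, 0, 0, 1.0), t, 1.0, 1.0, 0.5)
    return sd.Detection2D(fit, fp, accepted=True)


class TestAcceptanceRules:
    def test_all_conditions_met_accepted(self, family):
        det = apply_acceptance_rules(_fit(family[0]), threshold=1.0)
        assert det.accepted and det.reject_reasons == []

    def test_each_condition_rejected_with_its_own_reason(self, family):
        t = family[0]
        cfg = sd.DetectionConfig()
        small = sd.EllipseTemplate(19, 1.0, 0.0, t.fg_offsets[:19], t.bg_offsets)
        cases = {
            RULE_SIZE: apply_acceptance_rules(_fit(small), 1.0, cfg),
            RULE_ROUNDNESS: apply_acceptance_rules(
                _fit(sd.EllipseTemplate(t.area_px, 2.6, 0.0, t.fg_offsets, t.bg_offsets)),
                1.0,
                cfg,
            ),
            RULE_SNR_NULL: apply_acceptance_rules(_fit(t, snr1=0.9), 1.0, cfg),
            RULE_SLICE3: apply_acceptance_rules(_fit(t, snr1=2.0, snr3=1.0, snr7=0.5), 1.0, cfg),
            RULE_SLICE7: apply_acceptance_rules(_fit(t, snr1=2.0, snr3=2.0, snr7=2.5), 1.0, cfg),
        }
        for reason, det in cases.items():
            assert not det.accepted
            assert det.reject_reasons == [reason], reason

    def test_snr3_fraction_boundary(self, family):
        # reduction by exactly one third passes; reduction below 2/3 fails
        det = apply_acceptance_rules(_fit(family[0], snr1=3.0, snr3=2.0, snr7=1.0), 1.0)
        assert det.accepted
        det = apply_acceptance_rules(_fit(family[0], snr1=3.0, snr3=1.5, snr7=1.0), 1.0)
        assert det.reject_reasons == [RULE_SLICE3]

    def test_snr1_baseline_variant(self, family):
        cfg = sd.DetectionConfig(snr7_baseline="snr1")
        det = apply_acceptance_rules(_fit(family[0], snr1=2.0, snr3=2.2, snr7=2.1), 1.0, cfg)
        assert det.reject_reasons == [RULE_SLICE7]
        det = apply_acceptance_rules(_fit(family[0], snr1=2.0, snr3=2.2, snr7=1.9), 1.0, cfg)
        assert det.accepted

    def test_footprint_is_translated_template(self, family):
        t = family[0]
        det = apply_acceptance_rules(_fit(t, z=1, y=50, x=60), 1.0)
        assert det.footprint == {(50 + dy, 60 + dx) for dy, dx in t.fg_offsets}


class TestSliceAverages:
    def test_identical_planes_equalise_all_snrs(self, family):
        rng = np.random.default_rng(0)
        plane = rng.random((80, 80))
        vol = sd.ImageVolume(np.stack([plane] * 9))
        fit = _fit(family[5], z=4)
        s1, s3, s7 = slice_average_snrs(vol, fit)
        assert s1 == pytest.approx(s3, rel=1e-9)
        assert s1 == pytest.approx(s7, rel=1e-9)

    def test_truncation_at_stack_start(self, family):
        rng = np.random.default_rng(1)
        vol4 = sd.ImageVolume(rng.random((4, 80, 80)))
        fit = _fit(family[0], z=0)
        _, s3, s7 = slice_average_snrs(vol4, fit)
        # candidate at z=0 of a 4-plane stack: windows cover planes 0-1 / 0-3
        from synaptodetect.templates import extract_window, template_snr

        w3 = extract_window(vol4.voxels[:2].mean(axis=0), 40, 40, 32)
        w7 = extract_window(vol4.voxels.mean(axis=0), 40, 40, 32)
        assert s3 == pytest.approx(template_snr(w3, fit.template, "window"), rel=1e-9)
        assert s7 == pytest.approx(template_snr(w7, fit.template, "window"), rel=1e-9)

    def test_seeded_noise_single_plane_signal_drops_snr3(self, family):
        rng = np.random.default_rng(2)
        data = rng.normal(100, 5, size=(7, 80, 80))
        t = family[4]
        for dy, dx in t.fg_offsets:
            data[3, 40 + dy, 40 + dx] += 30.0
        fit = _fit(t, z=3)
        s1, s3, _ = slice_average_snrs(sd.ImageVolume(data), fit)
        assert s3 < s1


class TestNullThreshold:
    def test_constant_volume_threshold_zero(self, family):
        vol = sd.ImageVolume(np.full((3, 80, 80), 4.0))
        mask = build_exclusion_mask(vol)
        thr = snr_null_threshold(vol, family, mask, n=50, seed=0)
        assert thr == 0.0

    def test_deterministic_given_seed(self, small_gt, family):
        vol = small_gt.volume
        mask = build_exclusion_mask(vol)
        a = snr_null_threshold(vol, family, mask, n=100, seed=5)
        b = snr_null_threshold(vol, family, mask, n=100, seed=5)
        assert a == b
        c = snr_null_threshold(vol, family, mask, n=100, seed=6)
        assert a != c

    def test_small_n_matches_sort_interpolate_oracle(self, family, config):
        # with candidate locations given, the threshold is the percentile of
        # exactly those candidates' best-template SNRs
        rng = np.random.default_rng(3)
        vol = sd.ImageVolume(rng.random((2, 80, 80)) * 10)
        mask = build_exclusion_mask(vol)
        cands = [sd.CandidatePeak(z, y, x, 1.0) for z, y, x in
                 [(0, 10, 10), (0, 30, 50), (1, 20, 20), (1, 60, 60), (0, 70, 15)]]
        thr = snr_null_threshold(vol, family, mask, n=5, pct=90, seed=0, candidates=cands)
        snrs = sorted(
            sd.best_template(vol, p, family, config).snr1 for p in cands
        )
        # linear interpolation between the 4th and 5th order statistics
        expect = snrs[3] + 0.6 * (snrs[4] - snrs[3])
        assert thr == pytest.approx(expect, abs=2e-3)

    def test_too_few_valid_locations_error(self, family):
        vol = sd.ImageVolume(np.ones((1, 4, 4)))
        mask = build_exclusion_mask(vol)
        with pytest.raises(ValueError, match="valid null locations"):
            snr_null_threshold(vol, family, mask, n=300, seed=0)


class TestMergeAcrossPlanes:
    def test_overlapping_adjacent_planes_merge(self, family):
        d1 = _detection(2, {(5, 5), (5, 6)}, family=family)
        d2 = _detection(3, {(5, 6), (5, 7)}, family=family)
        merged = merge_across_planes([d1, d2])
        assert len(merged) == 1
        assert merged[0].z_span == 2

    def test_gap_plane_keeps_synapses_separate(self, family):
        d1 = _detection(2, {(5, 5)}, family=family)
        d2 = _detection(4, {(5, 5)}, family=family)
        merged = merge_across_planes([d1, d2])
        assert len(merged) == 2

    def test_chain_of_three_planes(self, family):
        dets = [
            _detection(1, {(5, 5), (5, 6)}, family=family),
            _detection(2, {(5, 6), (5, 7)}, family=family),
            _detection(3, {(5, 7), (5, 8)}, family=family),
        ]
        merged = merge_across_planes(dets)
        assert len(merged) == 1
        assert merged[0].z_span == 3
        assert merged[0].voxels == {
            (1, 5, 5), (1, 5, 6), (2, 5, 6), (2, 5, 7), (3, 5, 7), (3, 5, 8)
        }

    def test_min_overlap_pixels_respected(self, family):
        d1 = _detection(0, {(5, 5), (5, 6)}, family=family)
        d2 = _detection(1, {(5, 6), (5, 7)}, family=family)
        assert len(merge_across_planes([d1, d2], min_overlap_px=2)) == 2

    def test_intensity_weighted_centroid_and_total(self, family):
        data = np.zeros((2, 10, 10))
        data[0, 5, 5] = 1.0
        data[1, 5, 5] = 3.0
        vol = sd.ImageVolume(data)
        dets = [
            _detection(0, {(5, 5)}, family=family),
            _detection(1, {(5, 5)}, family=family),
        ]
        merged = merge_across_planes(dets, vol)
        assert merged[0].total_intensity == 4.0
        assert merged[0].centroid == pytest.approx((0.75, 5.0, 5.0))


class TestZSpanFilter:
    @pytest.mark.parametrize(
        "planes,kept",
        [((0,), False), ((0, 1), True), ((0, 1, 2, 3, 4, 5), True),
         ((0, 1, 2, 3, 4, 5, 6), False)],
    )
    def test_span_bounds(self, planes, kept):
        voxels = frozenset((z, 5, 5) for z in planes)
        syn = sd.Synapse3D(1, voxels, (0, 5, 5), 1.0)
        assert (len(filter_by_zspan([syn])) == 1) is kept

    def test_empty_input(self):
        assert filter_by_zspan([]) == []


class TestDetectPipeline:
    def test_all_zero_volume_no_synapses(self, family):
        vol = sd.ImageVolume(np.zeros((6, 96, 96)))
        synapses, report = sd.detect_pipeline(vol, sd.DetectionConfig(rng_seed=0), family=family)
        assert synapses == []
        assert report["n_synapses"] == 0

    def test_deterministic_given_seed(self, small_gt, family, small_detection):
        synapses, report = small_detection
        again, report2 = sd.detect_pipeline(
            small_gt.volume, sd.DetectionConfig(rng_seed=3), family=family
        )
        assert [s.voxels for s in again] == [s.voxels for s in synapses]
        assert report2["null_threshold"] == report["null_threshold"]

    def test_stage_counts_monotone(self, small_detection):
        _, report = small_detection
        assert (
            report["n_maxima"]
            >= report["n_after_prune"]
            >= report["n_after_exclusion"]
            >= report["n_accepted_2d"]
            >= report["n_merged_3d"]
            >= report["n_synapses"]
        )

    def test_final_synapses_span_2_to_6_planes(self, small_detection):
        synapses, _ = small_detection
        assert synapses, "expected detections on the shared fixture"
        for s in synapses:
            assert 2 <= s.z_span <= 6

    def test_raising_null_percentile_never_adds_synapses(self, small_gt, family):
        cfg90 = sd.DetectionConfig(rng_seed=3, null_percentile=90)
        cfg99 = sd.DetectionConfig(rng_seed=3, null_percentile=99)
        n90 = len(sd.detect_pipeline(small_gt.volume, cfg90, family=family)[0])
        n99 = len(sd.detect_pipeline(small_gt.volume, cfg99, family=family)[0])
        assert n99 <= n90
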