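import numpy as np
import pytest

from neurocollin import (
    FilterConfig,
    NeuronSegment,
    apply_filters,
    grey_threshold,
    measure_segments,
)


def seg(label, diameter=None, area=None, grey=150.0):
    """Build a NeuronSegment with a prescribed equivalent diameter or area."""
    if area is None:
        area = np.pi * (diameter / 2.0) ** 2
    d = 2.0 * np.sqrt(area / np.pi)
    return NeuronSegment(label=label, pixel_count=int(round(area)), area=area,
                         equiv_diameter=d, centroid=(0.0, 0.0), mean_grey=grey)


class TestMeasureSegments:
    def test_square_object_area_and_equiv_diameter(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[4:14, 6:16] = 1
        img = np.full((20, 20), 100, dtype=np.uint8)
        (s,) = measure_segments(mask, img, pixel_size=1.0)
        assert s.pixel_count == 100
        assert s.area == pytest.approx(100.0)
        assert s.equiv_diameter == pytest.approx(2 * np.sqrt(100 / np.pi), abs=1e-9)
        assert s.centroid == pytest.approx((10.5, 8.5))

    def test_pixel_size_scales_area_quadratically(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[2:6, 2:6] = 1
        img = np.zeros((10, 10), dtype=np.uint8)
        (s,) = measure_segments(mask, img, pixel_size=0.5)
        assert s.area == pytest.approx(16 * 0.25)

    def test_single_pixel_object(self):
        mask = np.zeros((5, 5), dtype=np.int32)
        mask[3, 1] = 1
        img = np.full((5, 5), 42, dtype=np.uint8)
        (s,) = measure_segments(mask, img)
        assert s.pixel_count == 1
        assert s.centroid == (1.0, 3.0)
        assert s.mean_grey == 42.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            measure_segments(np.zeros((4, 4), dtype=np.int32),
                             np.zeros((5, 5), dtype=np.uint8))

    def test_scene_areas_match_generator_truth_exactly(self, contaminated_scene):
        sc = contaminated_scene
        segments = measure_segments(sc.mask, sc.image)
        by_label = {s.label: s for s in segments}
        for row in sc.truth.itertuples():
            assert by_label[row.label].pixel_count == row.area_px


class TestGreyThreshold:
    def test_midpoint_of_neurons_and_background(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[0:5, :] = 1
        img = np.where(mask > 0, 200, 10).astype(np.uint8)
        t = grey_threshold(measure_segments(mask, img), img, mask)
        assert t == pytest.approx(105.0)

    def test_degenerate_uniform_image_flags_nothing(self):
        mask = np.zeros((6, 6), dtype=np.int32)
        mask[2:4, 2:4] = 1
        img = np.full((6, 6), 77, dtype=np.uint8)
        segments = measure_segments(mask, img)
        t = grey_threshold(segments, img, mask)
        assert t == 77.0
        res = apply_filters(segments, FilterConfig(), threshold=t)
        assert not any(r == "extracellular" for _, r in res.excluded)

    def test_fully_covered_partition_errors(self):
        mask = np.ones((4, 4), dtype=np.int32)
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(ValueError, match="background"):
            grey_threshold(measure_segments(mask, img), img, mask)

    def test_speckle_objects_fall_below_threshold(self, contaminated_scene):
        from neurocollin import prepare_image
        sc = contaminated_scene
        prepared = prepare_image(sc.image)
        segments = measure_segments(sc.mask, prepared)
        t = grey_threshold(segments, prepared, sc.mask)
        speckle = set(sc.truth.loc[sc.truth.cls == "speckle", "label"])
        for s in segments:
            if s.label in speckle:
                assert s.mean_grey < t


class TestApplyFilters:
    def test_threshold_arithmetic_on_stated_example(self):
        segments = [seg(1, 8.0), seg(2, 10.0), seg(3, 12.0)]
        res = apply_filters(segments, FilterConfig(grey_rule="off"))
        # diameters {8,10,12}: mean 10, sample SD 2
        assert res.thresholds_used["diam_lo"] == pytest.approx(10 - 0.75 * 2)
        assert res.thresholds_used["diam_hi"] == pytest.approx(10 + 1.75 * 2)

# Diameter sets whose mean and sample SD are exact in binary floating point,
# with one member landing exactly on a threshold:
#   LOWER: mean 14.75, SD 1  -> min 14.0 == mean - 0.75*SD
#   UPPER: mean 20,    SD 2  -> max 23.5 == mean + 1.75*SD
LOWER_BOUNDARY_DIAMS = [14.0, 14.25, 14.5, 14.5, 16.5]
UPPER_BOUNDARY_DIAMS = [23.5, 19.5, 19.0, 19.5, 18.5]


class TestBoundaryConvention(object):
    def test_lower_boundary_object_is_kept(self):
        cfg = FilterConfig(grey_rule="off", upper_diam_sd=10.0,
                           upper_area_sd=10.0)
        segments = [seg(i + 1, d) for i, d in enumerate(LOWER_BOUNDARY_DIAMS)]
        res = apply_filters(segments, cfg)
        assert len(res.excluded) == 0          # boundary equality kept

        shrunk = [seg(1, LOWER_BOUNDARY_DIAMS[0] - 1e-6)] + segments[1:]
        res2 = apply_filters(shrunk, cfg)
        reasons = {s.label: r for s, r in res2.excluded}
        assert reasons.get(1) == "too_small"

    def test_upper_boundary_object_is_kept(self):
        # isolate the diameter rule (the same object's quadratic area would
        # otherwise trip the area rule just past its own 1.75 SD cut)
        cfg = FilterConfig(grey_rule="off", upper_area_sd=10.0)
        segments = [seg(i + 1, d) for i, d in enumerate(UPPER_BOUNDARY_DIAMS)]
        res = apply_filters(segments, cfg)
        reasons = {s.label: r for s, r in res.excluded}
        assert 1 not in reasons                 # exactly at mean + 1.75 SD
        grown = [seg(1, UPPER_BOUNDARY_DIAMS[0] + 1e-6)] + segments[1:]
        res2 = apply_filters(grown, cfg)
        reasons2 = {s.label: r for s, r in res2.excluded}
        assert reasons2.get(1) == "too_large_diameter"

    def test_upper_area_boundary_object_is_kept(self):
        # areas chosen with the same exact-arithmetic structure
        cfg = FilterConfig(grey_rule="off", upper_diam_sd=10.0)
        areas = [a * 16.0 for a in UPPER_BOUNDARY_DIAMS]   # mean 320, SD 32
        segments = [seg(i + 1, area=a) for i, a in enumerate(areas)]
        res = apply_filters(segments, cfg)
        assert 1 not in {s.label for s, _ in res.excluded}
        grown = [seg(1, area=areas[0] + 1e-6)] + segments[1:]
        res2 = apply_filters(grown, cfg)
        reasons = {s.label: r for s, r in res2.excluded}
        assert reasons.get(1) == "too_large_area"

    def test_first_hit_reason_is_extracellular(self):
        segments = [seg(1, 2.0, grey=5.0), seg(2, 10.0), seg(3, 10.5),
                    seg(4, 11.0)]
        res = apply_filters(segments, FilterConfig(), threshold=100.0)
        reasons = {s.label: r for s, r in res.excluded}
        assert reasons[1] == "extracellular"    # small AND faint -> grey wins

    def test_size_statistics_exclude_extracellular_survivor_set(self):
        # a huge faint object must not corrupt the size statistics
        segments = [seg(1, 10.0), seg(2, 10.5), seg(3, 11.0),
                    seg(4, 60.0, grey=5.0)]
        res = apply_filters(segments, FilterConfig(), threshold=100.0)
        assert res.thresholds_used["diam_mean"] == pytest.approx(10.5)

    def test_partition_invariant_and_single_reason(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            segments = [seg(i + 1, float(rng.uniform(5, 30)),
                            grey=float(rng.uniform(0, 255)))
                        for i in range(n)]
            res = apply_filters(segments, FilterConfig(), threshold=120.0)
            assert len(res.kept) + len(res.excluded) == n
            kept_labels = {s.label for s in res.kept}
            excl_labels = {s.label for s, _ in res.excluded}
            assert not (kept_labels & excl_labels)

    def test_monotonicity_in_sd_multipliers(self, rng):
        segments = [seg(i + 1, float(rng.uniform(5, 30))) for i in range(40)]
        kept_sizes = []
        for mult in (2.0, 1.0, 0.5, 0.25):
            cfg = FilterConfig(lower_diam_sd=mult, upper_diam_sd=mult,
                               upper_area_sd=mult, grey_rule="off")
            kept_sizes.append(len(apply_filters(segments, cfg).kept))
        assert kept_sizes == sorted(kept_sizes, reverse=True)

    def test_grey_rule_off_never_flags_extracellular(self):
        segments = [seg(1, 10.0, grey=1.0), seg(2, 10.2, grey=2.0),
                    seg(3, 10.4, grey=3.0)]
        res = apply_filters(segments, FilterConfig(grey_rule="off"))
        assert not any(r == "extracellular" for _, r in res.excluded)

    def test_single_survivor_skips_size_rules_with_warning(self):
        segments = [seg(1, 10.0, grey=200.0), seg(2, 3.0, grey=5.0)]
        with pytest.warns(UserWarning, match="size"):
            res = apply_filters(segments, FilterConfig(), threshold=100.0)
        assert {s.label for s in res.kept} == {1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            apply_filters([], FilterConfig(), threshold=0.0)

    def test_planted_classes_recovered(self, contaminated_scene):
        from neurocollin import analyze_scene
        sc = contaminated_scene
        records, _ = analyze_scene(sc.image, sc.mask, sc.centerline)
        m = records.merge(sc.truth, on="label")
        expect = {"glia": {"too_small"},
                  "doublet": {"too_large_diameter", "too_large_area"},
                  "speckle": {"extracellular"},
                  "neuron": {"kept"}}
        for cls, grp in m.groupby("cls"):
            got = np.where(grp.status == "kept", "kept", grp.reason)
            agreement = np.mean([g in expect[cls] for g in got])
            assert agreement >= 0.9, f"{cls}: {agreement}"
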