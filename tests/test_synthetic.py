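import numpy as np
import pandas as pd
import pytest

from neurocollin import (
    ArcCurve,
    LineCurve,
    SceneSpec,
    SineCurve,
    circular_variance,
    generate_angle_sample,
    generate_multilevel_dataset,
    generate_scene,
)
from neurocollin.angles import axial_difference, fold_axial


def arc_spec(**kw):
    base = dict(curve=ArcCurve((0.0, 0.0), 400.0, (20.0, 160.0)),
                n_neurons=40, seed=0)
    base.update(kw)
    return SceneSpec(**base)


class TestGenerateScene:
    def test_same_seed_is_bit_identical(self):
        a = generate_scene(arc_spec(seed=5, n_glia=4, n_speckle=3))
        b = generate_scene(arc_spec(seed=5, n_glia=4, n_speckle=3))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask.labels, b.mask.labels)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = generate_scene(arc_spec(seed=5))
        b = generate_scene(arc_spec(seed=6))
        assert not np.array_equal(a.mask.labels, b.mask.labels)

    def test_class_bookkeeping(self):
        sc = generate_scene(arc_spec(n_neurons=40, n_glia=10, n_doublets=5))
        assert len(sc.truth) == 55
        counts = sc.truth.cls.value_counts()
        assert counts["neuron"] == 40
        assert counts["glia"] == 10
        assert counts["doublet"] == 5

    def test_label_truth_mapping_bijective(self):
        sc = generate_scene(arc_spec(n_glia=3, n_speckle=3))
        mask_labels = set(np.unique(sc.mask.labels)) - {0}
        assert mask_labels == set(sc.truth.label)

    def test_noise_free_orientations_equal_local_normal(self):
        spec = arc_spec(kappa=None)
        sc = generate_scene(spec)
        for row in sc.truth.itertuples():
            normal = spec.curve.normal_angle(row.t)
            assert axial_difference(row.angle_true_deg, normal) < 1e-9

    def test_neurons_lie_within_layer_width(self):
        spec = arc_spec(kappa=None)
        sc = generate_scene(spec)
        for row in sc.truth.itertuples():
            _, dist = _nearest_on_curve(spec.curve, (row.x, row.y), sc)
            assert dist <= spec.layer_width_um / 2 + 1.0

    def test_truth_areas_match_mask(self):
        sc = generate_scene(arc_spec(n_doublets=3))
        for row in sc.truth.itertuples():
            assert (sc.mask.labels == row.label).sum() == row.area_px

    def test_overcrowding_raises_helpful_error(self):
        spec = arc_spec(curve=ArcCurve((0.0, 0.0), 60.0, (60.0, 120.0)),
                        n_neurons=400)
        with pytest.raises(RuntimeError, match="density"):
            generate_scene(spec)

    @pytest.mark.parametrize("curve", [
        LineCurve((0.0, 0.0), (600.0, 0.0)),
        SineCurve((0.0, 0.0), length=600.0, amplitude=60.0, period=300.0),
    ])
    def test_alternative_curves_render(self, curve):
        sc = generate_scene(arc_spec(curve=curve, n_neurons=25, kappa=None))
        assert sc.mask.n_objects == 25

    def test_triangle_shape_orientation_recoverable(self):
        from neurocollin import fit_ellipses
        sc = generate_scene(arc_spec(shape="triangle", kappa=None, n_neurons=30))
        fits = fit_ellipses(sc.mask.labels).set_index("label")
        m = sc.truth.set_index("label").join(fits, rsuffix="_fit")
        err = axial_difference(m["unco_deg"], m["angle_true_deg"])
        assert np.nanmedian(err) < 3.0


def _nearest_on_curve(curve, p, scene):
    from neurocollin import nearest_point_on_polyline
    return nearest_point_on_polyline(p, scene.centerline)


class TestAngleSample:
    def test_uniform_limit_has_unit_circular_variance(self):
        angles = generate_angle_sample(100_000, 90.0, kappa=0.0, seed=1)
        assert circular_variance(angles) == pytest.approx(1.0, abs=0.01)

    def test_high_concentration_stays_near_mean(self):
        angles = generate_angle_sample(5000, 37.0, kappa=100.0, seed=2)
        assert axial_difference(angles, 37.0).mean() < 6.0

    def test_single_draw_in_axial_range(self):
        a = generate_angle_sample(1, 10.0, kappa=4.0, seed=3)
        assert a.shape == (1,)
        assert 0 <= a[0] < 180

    def test_mean_direction_matches_mu(self):
        angles = generate_angle_sample(20_000, 140.0, kappa=6.0, seed=4)
        doubled = np.radians(2 * angles)
        mean_dir = np.degrees(np.arctan2(np.sin(doubled).mean(),
                                         np.cos(doubled).mean())) / 2 % 180
        assert axial_difference(mean_dir, 140.0) < 1.0


class TestMultilevelDataset:
    def test_zero_variances_and_effects_constant(self):
        df = generate_multilevel_dataset(k_subregions=2, n_cases=2, n_slides=2,
                                         sigma_case=0, sigma_slide=0,
                                         sigma_resid=0, n_per_cell=3, seed=0)
        assert df["dev_deg"].nunique() == 1

    def test_determinism(self):
        a = generate_multilevel_dataset(seed=9)
        b = generate_multilevel_dataset(seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_design_is_fully_crossed(self):
        df = generate_multilevel_dataset(k_subregions=3, n_cases=4, n_slides=2,
                                         n_per_cell=5, seed=1)
        cells = df.groupby(["subregion", "case_id", "slide_id"]).size()
        assert len(cells) == 3 * 4 * 2
        assert (cells == 5).all()

    def test_values_truncated_to_valid_range(self):
        df = generate_multilevel_dataset(baseline=5.0, sigma_resid=40.0, seed=2)
        assert df["dev_deg"].between(0, 90).all()


class TestRotateScene:
    def test_quarter_turn_is_exact(self, noise_free_arc_scene):
        from neurocollin import rotate_label_scene
        sc = noise_free_arc_scene
        rot, _ = rotate_label_scene(sc.mask, sc.centerline.vertices, 90.0)
        for lab in (1, 2, 3):
            assert (rot == lab).sum() == (sc.mask.labels == lab).sum()

    def test_vertices_rotate_rigidly(self, noise_free_arc_scene):
        from neurocollin import rotate_label_scene
        sc = noise_free_arc_scene
        _, v = rotate_label_scene(sc.mask, sc.centerline.vertices, 33.0)
        d0 = np.linalg.norm(np.diff(sc.centerline.vertices, axis=0), axis=1)
        d1 = np.linalg.norm(np.diff(v, axis=0), axis=1)
        assert np.allclose(d0, d1, atol=1e-9)
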