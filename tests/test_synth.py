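import json

import numpy as np
import pytest

from nucseg.core import mask_to_contours
from nucseg.metrics import nsi_pair
from nucseg.synth import (BlebSpec, FieldSpec, NucleusSpec, TouchingPair,
                          classification_specs, gt_from_mask,
                          pseudo_observers, render_field,
                          segmentation_fields, standard_benchmark,
                          watershed_battery)
from nucseg.thresholds import auto_threshold
from nucseg.watershed import median_decay_ratio, watershed_candidates


def simple_spec(**kw):
    nuc = NucleusSpec(center_um=(14.0, 14.0), semi_axes_um=(5.0, 4.0))
    defaults = dict(shape_px=(140, 140), nuclei=(nuc,), seed=5)
    defaults.update(kw)
    return FieldSpec(**defaults)


class TestRenderField:
    def test_deterministic_given_seed(self):
        a, _, _ = render_field(simple_spec())
        b, _, _ = render_field(simple_spec())
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seed_changes_noise(self):
        a, _, _ = render_field(simple_spec(seed=5))
        b, _, _ = render_field(simple_spec(seed=6))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_ellipse_mask_area_matches_geometry(self):
        _, mask, _ = render_field(simple_spec())
        expect = np.pi * 5.0 * 4.0 / 0.2 ** 2
        assert (mask.labels > 0).sum() == pytest.approx(expect, rel=0.02)

    def test_dim_bleb_below_body_otsu_threshold(self, blebbed_field):
        """The 30%-intensity bleb sits below the image's Otsu threshold --
        the failure mode two-pass segmentation exists to fix."""
        img = blebbed_field["image"]
        spec = blebbed_field["spec"]
        thr = auto_threshold(img.pixels, "otsu")
        assert spec.nuclei[0].blebs[0].intensity_fraction * \
            spec.nuclei[0].body_intensity < thr

    def test_bleb_pixels_included_in_ground_truth(self, blebbed_field):
        nuc = blebbed_field["spec"].nuclei[0]
        body_only = NucleusSpec(center_um=nuc.center_um,
                                semi_axes_um=nuc.semi_axes_um)
        _, body_mask, _ = render_field(FieldSpec(
            shape_px=(140, 140), nuclei=(body_only,), gaussian_sd=0,
            poisson=False, blur_sigma_um=0, seed=0))
        mask = blebbed_field["mask"]
        bleb_px = (mask.labels > 0) & ~(body_mask.labels > 0)
        assert bleb_px.sum() > 100
        assert (mask.labels[bleb_px] == 1).all()

    @pytest.mark.parametrize("valley", [0.3, 0.4, 0.5])
    def test_touching_pair_valley_ratio_within_tolerance(self, valley):
        a = NucleusSpec(center_um=(11.0, 16.0), semi_axes_um=(5.0, 4.5))
        b = NucleusSpec(center_um=(20.4, 16.0), semi_axes_um=(4.8, 4.3))
        spec = FieldSpec(shape_px=(160, 160), nuclei=(a, b),
                         touching_pairs=(TouchingPair(0, 1, valley),),
                         gaussian_sd=0, poisson=False, seed=0)
        img, mask, _ = render_field(spec)
        _, lines = watershed_candidates(mask.labels > 0)
        assert len(lines) == 1
        ratio = median_decay_ratio(img, next(iter(lines.values())))
        assert ratio == pytest.approx(valley, abs=0.05)

    def test_undeclared_overlap_rejected(self):
        a = NucleusSpec(center_um=(12.0, 14.0), semi_axes_um=(5.0, 4.0))
        b = NucleusSpec(center_um=(18.0, 14.0), semi_axes_um=(5.0, 4.0))
        with pytest.raises(ValueError, match="overlap"):
            render_field(FieldSpec(shape_px=(160, 160), nuclei=(a, b), seed=0))

    def test_resolution_consistency_of_um_features(self):
        """Halving the pixel size changes um-denominated measurements < 2%."""
        from nucseg.features import shape_features
        areas = []
        for ps, shape in ((0.2, (140, 140)), (0.1, (280, 280))):
            spec = FieldSpec(shape_px=shape, pixel_size_um=ps,
                             nuclei=(NucleusSpec(center_um=(14.0, 14.0),
                                                 semi_axes_um=(5.0, 4.0)),),
                             gaussian_sd=0, poisson=False, seed=0)
            _, mask, _ = render_field(spec)
            c = mask_to_contours(mask)[0]
            areas.append(shape_features(c, ps)["area_um2"])
        assert areas[1] == pytest.approx(areas[0], rel=0.02)


class TestPseudoObservers:
    def test_pairwise_nsi_in_expected_band(self):
        spec = simple_spec()
        _, mask, _ = render_field(spec)
        gtset = pseudo_observers(gt_from_mask(mask), seed=42)
        vals = []
        for k in (1, 2):
            for l in range(k + 1, 4):
                vals.append(nsi_pair(gtset.contour(k, 1), gtset.contour(l, 1)))
        assert all(0.02 <= v <= 0.15 for v in vals)


class TestBenchmarkSpecs:
    def test_manifest_deterministic(self):
        a = standard_benchmark(seed=1)["manifest"]
        b = standard_benchmark(seed=1)["manifest"]
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_classification_set_balance(self):
        specs = classification_specs(seed=1, n_per_class=30)
        labels = [s.nuclei[0].class_label for s in specs]
        assert labels.count("normal") == 30
        assert labels.count("dysmorphic") == 30

    def test_segmentation_fields_counts_and_margins(self):
        fields = segmentation_fields(seed=1, n_normal=10, n_dysmorphic=10)
        classes = [n.class_label for f in fields for n in f.nuclei]
        assert classes.count("normal") == 10
        assert classes.count("dysmorphic") == 10
        for f in fields:
            h, w = f.shape_px
            for n in f.nuclei:
                x, y = n.center_um
                ext = n.max_extent_um()
                assert ext < x / 1 and x + ext < w * f.pixel_size_um
                assert ext < y / 1 and y + ext < h * f.pixel_size_um

    def test_watershed_battery_composition(self):
        items = watershed_battery(seed=2, n_pairs=4, n_blebbed=3)
        assert sum(1 for i in items if i["expected"] == "split") == 4
        assert sum(1 for i in items if i["expected"] == "merge") == 3
        for item in items:
            if item["expected"] == "split":
                assert item["valley_ratio"] <= 0.5
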