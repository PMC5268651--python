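import numpy as np
import pytest

from nucseg.core import CalibratedImage, NucleusContour
from nucseg.features import (FeatureConfig, efd_features, extract_all,
                             glcm_features, shape_features, total_curvature)
from nucseg.synth import FieldSpec, NucleusSpec, bleb_shape_family, \
    gt_from_mask, render_field

from conftest import circle_contour, square_contour


def transform_contour(c, angle=0.0, scale=1.0, shift=(0, 0), roll=0):
    pts = np.roll(c.points, roll, axis=0) * scale
    co, so = np.cos(angle), np.sin(angle)
    rot = pts @ np.array([[co, so], [-so, co]])
    return NucleusContour(points=rot + np.array(shift), stage=c.stage,
                          nucleus_id=c.nucleus_id)


def lobed_contour(n_lobes=6, base=10.0, amp=1.0, n=720):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = base + amp * np.cos(n_lobes * t)
    pts = np.column_stack([40 + r * np.cos(t), 40 + r * np.sin(t)])
    return NucleusContour(points=pts, stage="refined", nucleus_id=1)


class TestShapeFeatures:
    def test_circle_limit_values(self):
        c = circle_contour(60, 60, 50, n=720)   # 10 um radius at 0.2 um/px
        f = shape_features(c, 0.2)
        assert f["circularity"] >= 0.99
        assert f["solidity"] >= 0.99
        assert f["area_um2"] == pytest.approx(np.pi * 100, rel=0.01)
        assert f["ellipse_major_um"] == pytest.approx(20, rel=0.05)

    def test_square_circularity_closed_form(self):
        f = shape_features(square_contour(5, 5, 20), 1.0)
        assert f["circularity"] == pytest.approx(np.pi / 4, rel=1e-3)
        assert f["area_um2"] == pytest.approx(400)
        assert f["perimeter_um"] == pytest.approx(80)

    def test_blebbed_polygon_less_solid_than_hull(self):
        c = lobed_contour(n_lobes=5, amp=2.0)
        f = shape_features(c, 1.0)
        assert f["solidity"] < 0.95

    def test_translation_invariance_and_scaling_laws(self):
        c = lobed_contour()
        f0 = shape_features(c, 1.0)
        f_shift = shape_features(transform_contour(c, shift=(7, -3)), 1.0)
        for k in ("area_um2", "perimeter_um", "circularity", "solidity"):
            assert f_shift[k] == pytest.approx(f0[k], rel=1e-6)
        f_scaled = shape_features(transform_contour(c, scale=2.0), 1.0)
        assert f_scaled["area_um2"] == pytest.approx(4 * f0["area_um2"], rel=1e-3)
        assert f_scaled["perimeter_um"] == pytest.approx(
            2 * f0["perimeter_um"], rel=1e-3)


class TestTotalCurvature:
    @pytest.mark.parametrize("contour", [
        circle_contour(40, 40, 20, n=720),
        square_contour(10, 10, 30),
        NucleusContour(points=np.column_stack(
            [40 + 15 * np.cos(np.linspace(0, 2 * np.pi, 720, endpoint=False)),
             40 + 9 * np.sin(np.linspace(0, 2 * np.pi, 720, endpoint=False))]),
            stage="refined", nucleus_id=1),
    ])
    def test_convex_contour_turns_two_pi(self, contour):
        assert total_curvature(contour, 1.0, step_um=0.5) == pytest.approx(
            2 * np.pi, rel=0.01)

    def test_lobed_ellipse_exceeds_two_pi_and_matches_dense_oracle(self):
        c = lobed_contour(n_lobes=6, base=12, amp=1.0, n=2880)
        coarse = total_curvature(c, 1.0, step_um=0.5)
        assert coarse > 2 * np.pi
        # independent dense finite-difference integral of |dtheta|
        pts = c.points
        seg = np.roll(pts, -1, axis=0) - pts
        th = np.arctan2(seg[:, 1], seg[:, 0])
        dth = np.diff(np.concatenate([th, th[:1]]))
        dense = np.abs((dth + np.pi) % (2 * np.pi) - np.pi).sum()
        assert coarse == pytest.approx(dense, rel=0.02)

    def test_too_short_contour_rejected(self):
        with pytest.raises(ValueError):
            total_curvature(circle_contour(5, 5, 0.2, n=16), 1.0, step_um=0.5)


class TestEFD:
    def test_circle_scores_near_zero_and_harmonic_one_dominates(self):
        """A circle carries no information beyond harmonic 1; eccentric
        ellipses keep a small odd-harmonic tail inherent to the arc-length
        parametrization, far below any blebbed shape."""
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        circle = NucleusContour(points=np.column_stack(
            [50 + 20 * np.cos(t), 50 + 20 * np.sin(t)]),
            stage="refined", nucleus_id=1)
        _, circle_sum = efd_features(circle)
        assert circle_sum < 0.001
        ellipse = NucleusContour(points=np.column_stack(
            [50 + 20 * np.cos(t), 50 + 17 * np.sin(t)]),
            stage="refined", nucleus_id=1)
        amps, ellipse_sum = efd_features(ellipse)
        assert ellipse_sum < 0.05
        assert amps[0] > 10 * ellipse_sum

    def test_rotation_scale_and_start_point_invariance(self):
        c = lobed_contour(n_lobes=4, amp=1.5)
        amps0, sum0 = efd_features(c)
        moved = transform_contour(c, angle=np.deg2rad(37), scale=1.7,
                                  shift=(11, -4), roll=41)
        amps1, sum1 = efd_features(moved)
        assert np.allclose(amps0, amps1, atol=1e-6)
        assert sum1 == pytest.approx(sum0, abs=1e-6)

    def test_summed_efd_increases_with_bleb_amplitude(self):
        sums = [efd_features(c)[1] for c in bleb_shape_family()]
        assert all(np.diff(sums) > 0)


class TestGLCM:
    def test_constant_patch(self):
        px = np.full((32, 32), 77.0)
        mask = np.zeros((32, 32), bool)
        mask[4:28, 4:28] = True
        f = glcm_features(px, mask)
        assert f["entropy"] == 0.0
        assert f["asm"] == 1.0
        assert f["contrast"] == 0.0

    def test_rotation_invariance_under_quarter_turn(self, rng):
        px = rng.uniform(0, 255, (40, 40))
        mask = np.zeros((40, 40), bool)
        mask[6:34, 6:34] = True
        f0 = glcm_features(px, mask)
        f1 = glcm_features(np.rot90(px).copy(), np.rot90(mask).copy())
        for k in f0:
            assert f1[k] == pytest.approx(f0[k], abs=1e-10)

    def test_checkerboard_contrast_matches_hand_built_matrix(self):
        yy, xx = np.mgrid[0:32, 0:32]
        board = ((xx + yy) % 2).astype(float) * 100
        mask = np.ones((32, 32), bool)
        f = glcm_features(board, mask, levels=2, distance_px=1)
        # at distance 1, angle 0: all pairs differ by one level -> contrast 1;
        # diagonal angles pair equal levels -> contrast 0; average = 0.5
        assert f["contrast"] == pytest.approx(0.5, abs=1e-10)
        assert f["entropy"] > 0

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.zeros((16, 16)), np.zeros((16, 16), bool))


class TestExtractAll:
    def _field(self, **kw):
        nuc = NucleusSpec(center_um=(10.0, 10.0), semi_axes_um=(4.0, 3.2), **kw)
        nuc2 = NucleusSpec(center_um=(24.0, 24.0), semi_axes_um=(4.2, 3.5))
        return render_field(FieldSpec(shape_px=(170, 170), nuclei=(nuc, nuc2),
                                      seed=21))

    def test_complete_rows_per_nucleus(self):
        img, mask, _ = self._field()
        df = extract_all(img, gt_from_mask(mask))
        assert len(df) == 2
        assert not df.isna().any().any()

    def test_border_nuclei_excluded_by_default(self):
        img, mask, _ = self._field()
        contours = gt_from_mask(mask)
        contours[0].border = True
        assert len(extract_all(img, contours)) == 1
        assert len(extract_all(img, contours,
                               FeatureConfig(include_border=True))) == 2

    def test_entropy_separates_ruffled_from_plain(self, rng):
        """Chromatin ruffling (intensity gradient) raises GLCM entropy even
        when the shape is identical."""
        vals = {"plain": [], "ruffled": []}
        for i in range(20):
            for kind in vals:
                nuc = NucleusSpec(
                    center_um=(10.0, 10.0), semi_axes_um=(4.0, 3.2),
                    orientation_rad=float(rng.uniform(0, np.pi)),
                    ruffling_gradient=0.5 if kind == "ruffled" else 0.0)
                img, mask, _ = render_field(FieldSpec(
                    shape_px=(100, 100), nuclei=(nuc,),
                    seed=int(rng.integers(2 ** 31))))
                df = extract_all(img, gt_from_mask(mask))
                vals[kind].append(df.glcm_entropy.iloc[0])
        plain, ruff = np.array(vals["plain"]), np.array(vals["ruffled"])
        auc = np.mean(ruff[:, None] > plain[None, :]) \
            + 0.5 * np.mean(ruff[:, None] == plain[None, :])
        assert auc > 0.9
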