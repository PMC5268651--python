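import numpy as np
import pytest

from nucseg.core import GroundTruthSet, NucleusContour
from nucseg.metrics import (ahd, directed_avg_distance, match_contours, nsi,
                            nsi_pair, positive_control, scale_and_error,
                            validate)

from conftest import circle_contour, square_contour


def shifted(contour, dx, dy, nucleus_id=None):
    return NucleusContour(points=contour.points + np.array([dx, dy]),
                          stage=contour.stage,
                          nucleus_id=nucleus_id or contour.nucleus_id)


def brute_force_directed(A, B, ps=1.0):
    a = A.resample(0.5)
    b = B.resample(0.5)
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1).mean() * ps


class TestDirectedDistance:
    def test_identical_contours_zero(self):
        c = circle_contour(20, 20, 10)
        assert directed_avg_distance(c, c) == pytest.approx(0.0, abs=1e-9)

    def test_concentric_circles(self):
        a = circle_contour(30, 30, 10, n=256)
        b = circle_contour(30, 30, 12, n=256)
        assert directed_avg_distance(a, b, 0.5) == pytest.approx(1.0, abs=0.02)
        assert directed_avg_distance(b, a, 0.5) == pytest.approx(1.0, abs=0.02)

    def test_translated_square_matches_all_pairs_oracle(self):
        a = square_contour(10, 10, 8)
        b = shifted(a, 3, 0)
        for x, y in ((a, b), (b, a)):
            mine = directed_avg_distance(x, y, 0.5)
            assert 0 <= mine <= 3 * 0.5
            assert mine == pytest.approx(brute_force_directed(x, y, 0.5),
                                         abs=1e-9)


class TestAHD:
    def test_identical_ground_truths_zero(self):
        c = circle_contour(20, 20, 10)
        assert ahd(c, [c, c, c]) == pytest.approx(0.0, abs=1e-9)

    def test_single_observer_directed_max(self):
        c = square_contour(10, 10, 8)
        g = shifted(c, 2, 0)
        expect = max(brute_force_directed(c, g), brute_force_directed(g, c))
        assert ahd(c, [g]) == pytest.approx(expect, abs=1e-9)

    def test_three_observers_average(self):
        c = circle_contour(30, 30, 10, n=256)
        gts = [circle_contour(30, 30, r, n=256) for r in (11, 12, 13)]
        per = [max(directed_avg_distance(c, g), directed_avg_distance(g, c))
               for g in gts]
        assert ahd(c, gts) == pytest.approx(np.mean(per), abs=1e-12)

    def test_symmetric_under_swap(self, rng):
        for _ in range(5):
            a = circle_contour(*rng.uniform(20, 30, 2), rng.uniform(5, 10))
            b = circle_contour(*rng.uniform(20, 30, 2), rng.uniform(5, 10))
            assert ahd(a, [b]) == pytest.approx(ahd(b, [a]), abs=1e-12)

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="no ground truth"):
            ahd(circle_contour(20, 20, 10), [])


class TestNSI:
    def test_identical_zero(self):
        c = square_contour(5, 5, 10)
        assert nsi_pair(c, c) == 0.0

    def test_disjoint_one(self):
        a = square_contour(2, 2, 6)
        b = square_contour(20, 20, 6)
        assert nsi_pair(a, b) == 1.0

    def test_half_overlapping_equal_squares(self):
        # 10x10 squares sharing half their area: (200 - 100) / 200 = 0.5
        a = square_contour(4.5, 4.5, 10)
        b = shifted(a, 5, 0)
        assert nsi_pair(a, b) == pytest.approx(0.5, abs=0.01)

    def test_bounded_and_averaged(self, rng):
        c = circle_contour(20, 20, 8)
        gts = [shifted(c, dx, 0) for dx in (1, 2)]
        vals = [nsi_pair(c, g) for g in gts]
        assert all(0 <= v <= 1 for v in vals)
        assert nsi(c, gts) == pytest.approx(np.mean(vals))


class TestPositiveControl:
    def _gts(self, offsets):
        base = circle_contour(30, 30, 10, n=128)
        return GroundTruthSet(contours_by_observer={
            k + 1: [shifted(base, dx, dy)]
            for k, (dx, dy) in enumerate(offsets)})

    def test_identical_observers_degenerate(self):
        gt = self._gts([(0, 0), (0, 0), (0, 0)])
        ahd_pc, nsi_pc = positive_control(gt, 1)
        assert ahd_pc == pytest.approx(0, abs=1e-9)
        rec = scale_and_error(1, (0.5, 0.1), (ahd_pc, nsi_pc))
        assert rec.degenerate_pc

    def test_two_observers_single_pair(self):
        gt = self._gts([(0, 0), (2, 0)])
        a, b = (gt.contour(1, 1), gt.contour(2, 1))
        expect = max(directed_avg_distance(a, b), directed_avg_distance(b, a))
        assert positive_control(gt, 1)[0] == pytest.approx(expect, abs=1e-12)

    def test_three_observers_mean_of_unordered_pairs(self):
        gt = self._gts([(0, 0), (2, 0), (0, 3)])
        from itertools import combinations
        ahd_vals, nsi_vals = [], []
        for k, l in combinations([1, 2, 3], 2):
            a, b = gt.contour(k, 1), gt.contour(l, 1)
            ahd_vals.append(max(directed_avg_distance(a, b),
                                directed_avg_distance(b, a)))
            nsi_vals.append(nsi_pair(a, b))
        pc = positive_control(gt, 1)
        assert pc[0] == pytest.approx(np.mean(ahd_vals), abs=1e-12)
        assert pc[1] == pytest.approx(np.mean(nsi_vals), abs=1e-12)


class TestScaling:
    def test_raw_equals_pc_gives_unit_error(self):
        rec = scale_and_error(1, (0.3, 0.05), (0.3, 0.05))
        assert rec.error == pytest.approx(1.0)

    def test_zero_raw_gives_zero_error(self):
        rec = scale_and_error(1, (0.0, 0.0), (0.4, 0.1))
        assert rec.error == 0.0

    def test_mixed_scaling_arithmetic(self):
        rec = scale_and_error(1, (0.8, 0.05), (0.4, 0.1))
        assert rec.ahd_scaled == pytest.approx(2.0)
        assert rec.nsi_scaled == pytest.approx(0.5)
        assert rec.error == pytest.approx(1.25)

    def test_scale_equivariance(self):
        a = scale_and_error(1, (0.3, 0.06), (0.2, 0.04))
        b = scale_and_error(1, (0.6, 0.12), (0.2, 0.04))
        assert b.error == pytest.approx(2 * a.error)


class TestValidate:
    def test_overlap_matching_and_records(self):
        pred = [circle_contour(20, 20, 9, nucleus_id=5),
                circle_contour(50, 50, 8, nucleus_id=6)]
        base1 = circle_contour(20, 20, 10, nucleus_id=1)
        base2 = circle_contour(50, 50, 9, nucleus_id=2)
        gt = GroundTruthSet(contours_by_observer={
            k: [shifted(base1, 0.5 * k, 0), shifted(base2, 0, 0.5 * k)]
            for k in (1, 2, 3)})
        df = validate(pred, gt, (80, 80), pixel_size_um=0.5)
        assert len(df) == 2
        assert set(df.nucleus_id) == {1, 2}
        assert (df.error > 0).all()

    def test_unmatched_prediction_not_scored(self):
        pred = [circle_contour(20, 20, 9, nucleus_id=1),
                circle_contour(70, 70, 5, nucleus_id=2)]   # nothing there
        base = circle_contour(20, 20, 10, nucleus_id=1)
        gt = GroundTruthSet(contours_by_observer={
            k: [shifted(base, 0.3 * k, 0)] for k in (1, 2)})
        df = validate(pred, gt, (90, 90))
        assert list(df.nucleus_id) == [1]
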