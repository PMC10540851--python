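"""Grid-search curve fitting, pair enumeration, and per-FA statistics."""

import math

import numpy as np
import pytest

import sftrace as sft
from sftrace.focal_adhesions import FocalAdhesion
from sftrace.imaging import ImagePlane
from sftrace.mask import CellMask
from sftrace.stressfibers import (
    CurveParams,
    FitGrid,
    PenaltyConfig,
    curve_family,
    max_curvature,
    overshoot,
    penalty,
    place_curve,
    relative_length,
    sample_intensity,
)


def brute_force_best(image, p_i, p_j, grid, pen, n_samples):
    """Independent scalar-path maximization with the documented tie-break."""
    d = math.hypot(p_j[0] - p_i[0], p_j[1] - p_i[1])
    candidates = []
    for a in grid.a_values:
        for theta in grid.theta_values:
            poly = curve_family(d, theta, a, n_samples)
            chi = overshoot(poly, d)
            placed = place_curve(poly, p_i, p_j)
            mean_arith, _ = sample_intensity(image, placed)
            params = CurveParams(d=d, theta=theta, a=a, n_samples=n_samples)
            total = (
                penalty(chi, 0.0, pen.amplitude)
                * penalty(relative_length(params), pen.t_length, pen.amplitude)
                * penalty(max_curvature(params), pen.t_curv, pen.amplitude)
            )
            score = mean_arith / total
            candidates.append((-score, abs(a), abs(theta), a, theta))
    candidates.sort()
    neg_score, _, _, a, theta = candidates[0]
    return -neg_score, a, theta


def _full_mask(shape):
    return CellMask(
        mask=np.ones(shape, dtype=bool), label=1, area=shape[0] * shape[1],
        centroid=(shape[1] / 2, shape[0] / 2), orientation=0.0,
        bbox=(0, 0, shape[1], shape[0]),
    )


def _fa(i, x, y):
    return FocalAdhesion(id=i, centroid=(x, y), area=30, major_axis=8,
                         minor_axis=4, aspect_ratio=2, orientation=0.0)


class TestFitBestCurve:
    def test_uniform_image_returns_straight_chord(self):
        img = ImagePlane(np.full((64, 64), 0.5))
        fc = sft.fit_best_curve(img, (10, 30), (50, 30))
        assert fc.params.a == 0.0
        assert fc.params.theta == 0.0
        assert fc.rel_length == pytest.approx(1.0)
        assert fc.penalty == 1.0

    def test_single_candidate_grid_scores_chord_mean(self):
        img = ImagePlane(np.full((32, 32), 0.25))
        grid = FitGrid(np.array([0.0]), np.array([0.0]))
        fc = sft.fit_best_curve(img, (4, 16), (28, 16), grid=grid)
        assert fc.score == pytest.approx(fc.mean_arith) == pytest.approx(0.25)

    def test_recovers_drawn_parabola_parameter(self):
        # stamp a bright stroke along a known (a0, 0) curve, fit, and expect
        # the returned a within one grid step of a0
        a0, d = 0.006, 120.0
        p_i, p_j = (20.0, 100.0), (140.0, 100.0)
        stroke = place_curve(curve_family(d, 0.0, a0, 1200), p_i, p_j)
        img = np.full((200, 200), 0.05)
        for x, y in stroke:
            img[int(round(y)), int(round(x))] = 0.95
        grid = FitGrid(np.linspace(-0.01, 0.01, 41), np.linspace(-0.3, 0.3, 11))
        fc = sft.fit_best_curve(ImagePlane(img), p_i, p_j, grid=grid, n_samples=240)
        step = 0.02 / 40
        assert abs(fc.params.a - a0) <= step + 1e-12

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        pen = PenaltyConfig()
        grid = FitGrid(np.linspace(-0.01, 0.01, 7), np.linspace(-0.4, 0.4, 5))
        n_checked = 0
        while n_checked < 30:
            img = ImagePlane(rng.random((48, 48)))
            p_i = rng.uniform(5, 43, 2)
            p_j = rng.uniform(5, 43, 2)
            if math.hypot(*(p_j - p_i)) < 3:
                continue
            fc = sft.fit_best_curve(img, p_i, p_j, grid=grid, pen=pen, n_samples=50)
            score, a, theta = brute_force_best(img, p_i, p_j, grid, pen, 50)
            assert fc.params.a == a
            assert fc.params.theta == theta
            assert fc.score == pytest.approx(score, rel=1e-12)
            n_checked += 1

    def test_score_equals_mean_over_penalty(self, rng):
        img = ImagePlane(rng.random((48, 48)))
        fc = sft.fit_best_curve(img, (5, 5), (40, 40))
        assert fc.score == pytest.approx(fc.mean_arith / fc.penalty, rel=1e-12)
        assert fc.penalty >= 1.0
        assert fc.rel_length >= 1 - 1e-9
        assert fc.max_curvature >= 0.0

    def test_polyline_endpoints_at_anchors(self, rng):
        img = ImagePlane(rng.random((64, 64)))
        p_i, p_j = (7.3, 12.1), (55.2, 48.9)
        fc = sft.fit_best_curve(img, p_i, p_j)
        assert np.linalg.norm(fc.polyline[0] - p_i) <= 1e-6
        assert np.linalg.norm(fc.polyline[-1] - p_j) <= 1e-6

    def test_coincident_anchors_rejected(self):
        with pytest.raises(ValueError):
            sft.fit_best_curve(ImagePlane(np.zeros((8, 8))), (3, 3), (3, 3))

    def test_penalty_monotone_in_violations(self):
        # same mean intensity, larger curvature violation -> lower score
        pen = PenaltyConfig(t_curv=0.001, amplitude=50.0)
        img = ImagePlane(np.full((64, 64), 0.5))
        mild = FitGrid(np.array([0.002]), np.array([0.0]))
        harsh = FitGrid(np.array([0.008]), np.array([0.0]))
        s1 = sft.fit_best_curve(img, (10, 32), (54, 32), grid=mild, pen=pen).score
        s2 = sft.fit_best_curve(img, (10, 32), (54, 32), grid=harsh, pen=pen).score
        assert s2 < s1


class TestFitAllPairs:
    def test_pair_count_and_sorting(self):
        img = ImagePlane(np.full((96, 96), 0.3))
        fas = [_fa(0, 20, 20), _fa(1, 70, 20), _fa(2, 45, 70)]
        curves = sft.fit_all_pairs(img, fas, _full_mask((96, 96)), accept_threshold=0.9)
        assert len(curves) == 3
        assert [(c.params.fa_i, c.params.fa_j) for c in curves] == [(0, 1), (0, 2), (1, 2)]

    def test_zero_or_one_fa_yields_no_pairs(self):
        img = ImagePlane(np.zeros((32, 32)))
        assert sft.fit_all_pairs(img, [], _full_mask((32, 32))) == []
        assert sft.fit_all_pairs(img, [_fa(0, 10, 10)], _full_mask((32, 32))) == []

    def test_d_max_restricts_pairs(self):
        img = ImagePlane(np.full((96, 96), 0.3))
        fas = [_fa(0, 10, 10), _fa(1, 30, 10), _fa(2, 90, 90)]
        curves = sft.fit_all_pairs(img, fas, _full_mask((96, 96)), d_max=30)
        assert [(c.params.fa_i, c.params.fa_j) for c in curves] == [(0, 1)]

    def test_centroid_outside_mask_rejected(self):
        img = ImagePlane(np.zeros((32, 32)))
        mask = np.zeros((32, 32), dtype=bool)
        mask[:16, :] = True
        cell = CellMask(mask=mask, label=1, area=int(mask.sum()), centroid=(16, 8),
                        orientation=0.0, bbox=(0, 0, 32, 16))
        with pytest.raises(ValueError, match="outside"):
            sft.fit_all_pairs(img, [_fa(0, 5, 5), _fa(1, 5, 28)], cell)

    def test_bright_stroke_pair_accepted_distant_fa_not(self, small_scene, small_result):
        # the rendered scene has two anchored strokes among four FAs: exactly
        # the two stroke pairs are accepted, none of the other four pairs
        accepted = [(c.params.fa_i, c.params.fa_j) for c in small_result.curves if c.accepted]
        assert len(accepted) == 2
        score = sft.score_against_truth(small_result.curves, small_scene)
        assert (score.true_positives, score.false_positives) == (2, 0)


class TestSfsPerFA:
    def _curves(self, pairs, accepted=True):
        out = []
        for i, j in pairs:
            fc = sft.fit_best_curve(
                ImagePlane(np.full((64, 64), 0.5)), (10 + i, 10), (20 + j, 40),
                grid=FitGrid(np.array([0.0]), np.array([0.0])), fa_i=i, fa_j=j,
            )
            from dataclasses import replace

            out.append(replace(fc, accepted=accepted))
        return out

    def test_no_accepted_curves(self):
        fas = [_fa(0, 1, 1), _fa(1, 2, 2)]
        counts, mean, sd = sft.sfs_per_fa(self._curves([(0, 1)], accepted=False), fas)
        assert counts.tolist() == [0, 0] and mean == 0.0 and sd == 0.0

    def test_triangle_counts(self):
        fas = [_fa(i, i, i) for i in range(3)]
        counts, mean, sd = sft.sfs_per_fa(self._curves([(0, 1), (0, 2), (1, 2)]), fas)
        assert counts.tolist() == [2, 2, 2]
        assert mean == 2.0 and sd == 0.0

    def test_single_curve_between_two(self):
        fas = [_fa(0, 1, 1), _fa(1, 2, 2)]
        counts, mean, _ = sft.sfs_per_fa(self._curves([(0, 1)]), fas)
        assert counts.tolist() == [1, 1] and mean == 1.0
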