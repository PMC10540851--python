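"""Anchored-parabola geometry, shape descriptors, and the penalty function."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sftrace as sft
from sftrace.imaging import ImagePlane
from sftrace.stressfibers import CurveParams

valid_d = st.floats(min_value=5.0, max_value=2000.0)
valid_theta = st.floats(min_value=-1.4, max_value=1.4)
valid_a = st.floats(min_value=-0.02, max_value=0.02)


class TestCurveFamily:
    def test_straight_chord(self):
        poly = sft.curve_family(50.0, 0.0, 0.0, 11)
        np.testing.assert_allclose(poly[:, 1], 0.0, atol=1e-12)
        np.testing.assert_allclose(poly[:, 0], np.linspace(0, 50, 11), atol=1e-12)

    def test_symmetric_arc_apex_at_midchord(self):
        poly = sft.curve_family(100.0, 0.0, 0.01, 1001)
        apex = np.argmax(np.abs(poly[:, 1]))
        assert poly[apex, 0] == pytest.approx(50.0, abs=0.2)
        # y = a x (x - d): apex depth a * (d/2)^2
        assert abs(poly[apex, 1]) == pytest.approx(0.01 * 50**2, rel=1e-3)

    @settings(derandomize=True, max_examples=200)
    @given(d=valid_d, theta=valid_theta, a=valid_a)
    def test_endpoint_constraint_across_domain(self, d, theta, a):
        poly = sft.curve_family(d, theta, a, 33)
        assert math.hypot(*poly[0]) <= 1e-6
        assert math.hypot(poly[-1, 0] - d, poly[-1, 1]) <= 1e-6

    def test_degenerate_theta_rejected(self):
        with pytest.raises(ValueError):
            sft.curve_family(10.0, math.pi / 2, 0.0, 8)


class TestPlaceCurve:
    def test_identity_and_rotation(self):
        poly = sft.curve_family(10.0, 0.0, 0.0, 5)
        same = sft.place_curve(poly, (0, 0), (10, 0))
        np.testing.assert_allclose(same, poly, atol=1e-12)
        vert = sft.place_curve(poly, (0, 0), (0, 10))
        np.testing.assert_allclose(vert[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(vert[:, 1], np.linspace(0, 10, 5), atol=1e-9)

    def test_rigid_transform_preserves_distances(self, rng):
        poly = sft.curve_family(37.0, 0.2, 0.005, 12)
        p_i = rng.uniform(0, 100, 2)
        direction = rng.standard_normal(2)
        direction /= np.linalg.norm(direction)
        p_j = p_i + 37.0 * direction
        placed = sft.place_curve(poly, p_i, p_j)
        d0 = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        d1 = np.linalg.norm(np.diff(placed, axis=0), axis=1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9)

    def test_coincident_or_mismatched_anchors_rejected(self):
        poly = sft.curve_family(10.0, 0.0, 0.0, 5)
        with pytest.raises(ValueError):
            sft.place_curve(poly, (3, 3), (3, 3))
        with pytest.raises(ValueError):
            sft.place_curve(poly, (0, 0), (11, 0))


class TestDescriptors:
    def test_straight_chord_values(self):
        p = CurveParams(d=80.0, theta=0.0, a=0.0)
        assert sft.relative_length(p) == 1.0
        assert sft.max_curvature(p) == 0.0

    def test_arc_length_against_dense_summation(self):
        p = CurveParams(d=100.0, theta=0.0, a=0.01)
        poly = sft.curve_family(100.0, 0.0, 0.01, 200001)
        numeric = np.hypot(*np.diff(poly, axis=0).T).sum() / 100.0
        assert sft.relative_length(p) == pytest.approx(numeric, rel=1e-4)

    @settings(derandomize=True, max_examples=60)
    @given(d=st.floats(20, 500), theta=st.floats(-0.6, 0.6), a=st.floats(-0.01, 0.01))
    def test_relative_length_at_least_one(self, d, theta, a):
        assert sft.relative_length(CurveParams(d=d, theta=theta, a=a)) >= 1 - 1e-9

    def test_vertex_in_span_gives_two_a(self):
        p = CurveParams(d=100.0, theta=0.0, a=0.004)
        assert sft.max_curvature(p) == pytest.approx(0.008, abs=1e-15)

    @settings(derandomize=True, max_examples=60)
    @given(d=st.floats(20, 500), theta=st.floats(-0.6, 0.6), a=st.floats(-0.01, 0.01))
    def test_max_curvature_matches_dense_sampling(self, d, theta, a):
        p = CurveParams(d=d, theta=theta, a=a)
        x1 = d * math.cos(theta)
        xs = np.linspace(0.0, x1, 100001)
        dense = (np.abs(2 * a) / (1 + (2 * a * xs + p.b) ** 2) ** 1.5).max()
        assert sft.max_curvature(p) == pytest.approx(dense, rel=1e-6, abs=1e-15)


class TestOvershoot:
    def test_chord_and_symmetric_arc_have_none(self):
        assert sft.overshoot(sft.curve_family(50, 0.0, 0.0, 9), 50) == 0.0
        assert sft.overshoot(sft.curve_family(50, 0.0, 0.015, 99), 50) == 0.0

    def test_direct_max_computation(self):
        poly = np.array([[0.0, 0.0], [55.0, 1.0], [50.0, 0.0]])
        assert sft.overshoot(poly, 50.0) == 5.0
        poly2 = np.array([[-2.5, 0.0], [25.0, 1.0], [50.0, 0.0]])
        assert sft.overshoot(poly2, 50.0) == 2.5


class TestPenalty:
    def test_below_threshold_is_one(self):
        for t in (0.1, 1.0, 10.0):
            for A in (1.0, 10.0, 50.0):
                assert sft.penalty(t / 2, t, A) == 1.0

    def test_continuity_at_threshold_and_unit_exponent(self):
        assert sft.penalty(1.3, 1.3, 50.0) == 1.0
        assert sft.penalty(1.3 + 1 / 50.0, 1.3, 50.0) == pytest.approx(math.e, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        chi1=st.floats(0, 5), chi2=st.floats(0, 5),
        t=st.floats(0, 2), A=st.floats(0.1, 60),
    )
    def test_monotone_and_at_least_one(self, chi1, chi2, t, A):
        lo, hi = sorted((chi1, chi2))
        assert 1.0 <= sft.penalty(lo, t, A) <= sft.penalty(hi, t, A)

    def test_multiplicative_accumulation(self):
        # accumulated penalties multiply: product equals exp of summed excesses
        A = 20.0
        p = sft.penalty(0.5, 0.0, A) * sft.penalty(1.4, 1.3, A) * sft.penalty(0.06, 0.05, A)
        assert p == pytest.approx(math.exp(A * (0.5 + 0.1 + 0.01)), rel=1e-9)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sft.penalty(1.0, 0.5, 0.0)


class TestPreprocessSF:
    def test_blank_image_passes_through_blank(self):
        out = sft.preprocess_sf(ImagePlane(np.zeros((32, 32))))
        assert out.data.max() == 0.0

    def test_degenerate_percentiles_named_in_error(self):
        img = np.full((64, 64), 0.5)
        img[0, 0] = 1.0  # non-constant, but P10 == P50 == 0.5
        with pytest.raises(ValueError, match="P10.*P50"):
            sft.preprocess_sf(ImagePlane(img))

    def test_neutral_weights_return_normalized_raw(self, rng):
        from sftrace.stressfibers import SFPreprocessConfig

        raw = rng.random((64, 64)) * 0.7
        cfg = SFPreprocessConfig(w_contrast=0.0, w_edge=0.0)
        out = sft.preprocess_sf(ImagePlane(raw), cfg)
        np.testing.assert_allclose(out.data, raw / raw.max(), atol=1e-12)

    def test_default_preprocessing_brightens_dim_fiber(self):
        # contrast-enhancement oracle: a dim stroke near a bright one gains
        # intensity on the unit scale (the stretch saturates both), which is
        # what makes low-intensity fibers detectable by a mean-intensity fit
        import math

        from sftrace.synth import CellBody, FABlob, GroundTruthSpec, Stroke

        spec = GroundTruthSpec(
            width=512, height=512,
            fa_blobs=(
                FABlob((120, 200), 18, 8, 0, 0.85), FABlob((390, 230), 18, 8, 0, 0.85),
                FABlob((120, 290), 18, 8, 0, 0.85), FABlob((390, 320), 18, 8, 0, 0.85),
            ),
            sf_strokes=(
                Stroke(0, 1, width_px=5, peak=0.95),
                Stroke(2, 3, width_px=5, peak=0.30),  # the dim fiber
            ),
            background=0.12, cell_body=CellBody((256, 256), 235, 200, 0.0),
            texture_periods=(60.25, 70.75),
        )
        _, sf_plane = sft.render_scene(spec)
        pre = sft.preprocess_sf(sf_plane)
        dim = spec.sf_strokes[1]
        p0 = spec.fa_blobs[dim.fa_i].center
        p1 = spec.fa_blobs[dim.fa_j].center
        d = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
        poly = sft.place_curve(sft.curve_family(d, dim.theta, dim.a, 300), p0, p1)
        raw_mean, _ = sft.sample_intensity(sf_plane, poly)
        pre_mean, _ = sft.sample_intensity(pre, poly)
        assert pre_mean > raw_mean


class TestSampleIntensity:
    def test_uniform_image(self):
        img = ImagePlane(np.full((32, 32), 0.6))
        # 3-4-5 direction keeps the anchor distance exactly 20
        poly = sft.place_curve(sft.curve_family(20, 0.1, 0.002, 50), (5, 5), (21, 17))
        ma, mg = sft.sample_intensity(img, poly)
        assert ma == pytest.approx(0.6)
        assert mg == pytest.approx(0.6)

    def test_alternating_pixel_centers(self):
        img = np.zeros((4, 8))
        img[1, ::2] = 0.2
        img[1, 1::2] = 0.4
        poly = np.array([[x, 1.0] for x in range(8)])
        ma, _ = sft.sample_intensity(ImagePlane(img), poly)
        assert ma == pytest.approx(0.3)

    def test_geometric_never_exceeds_arithmetic(self, rng):
        img = ImagePlane(rng.random((32, 32)))
        poly = np.column_stack([rng.uniform(0, 31, 40), rng.uniform(0, 31, 40)])
        ma, mg = sft.sample_intensity(img, poly)
        assert mg <= ma + 1e-12

    def test_out_of_bounds_counts_as_zero(self):
        img = ImagePlane(np.ones((8, 8)))
        poly = np.array([[100.0, 100.0], [120.0, 100.0]])
        ma, _ = sft.sample_intensity(img, poly)
        assert ma == 0.0
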