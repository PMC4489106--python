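import numpy as np
import pytest

from fishposture.midline import (
    BackboneFrame,
    FrameStack,
    SegmentationError,
    compute_spine_angles,
    extract_spine,
    fit_spline_sample,
    segment_and_skeletonize,
    subtract_background,
)
from fishposture.spine import InvalidInputError, SpineAngleMatrix
from fishposture.synthetic import render_fish_frames, roi_polygon, scoot_params
from fishposture.neuro import simulate_bout


def render_rod(length=80, width=5, size=(120, 120), value=200.0):
    img = np.zeros(size)
    r0 = size[0] // 2
    c0 = (size[1] - length) // 2
    img[r0 - width // 2 : r0 + width // 2 + 1, c0 : c0 + length] = value
    return img, r0


class TestBackgroundSubtraction:
    def test_uniform_stack_cancels_exactly(self):
        stack = FrameStack(frames=np.full((3, 50, 50), 37.0), frame_rate=500)
        roi = np.array([[10.0, 10.0], [40.0, 10.0], [40.0, 40.0], [10.0, 40.0]])
        out = subtract_background(stack, roi)
        assert np.allclose(out.frames, 0.0, atol=1e-6)

    def test_shape_preserved(self):
        stack = FrameStack(frames=np.random.default_rng(0).random((4, 30, 40)), frame_rate=500)
        roi = np.array([[5.0, 5.0], [25.0, 5.0], [25.0, 25.0], [5.0, 25.0]])
        out = subtract_background(stack, roi)
        assert out.frames.shape == stack.frames.shape

    def test_degenerate_roi_rejected(self):
        stack = FrameStack(frames=np.zeros((2, 30, 30)), frame_rate=500)
        roi = np.array([[5.0, 5.0], [5.5, 5.0], [5.0, 5.5]])
        with pytest.raises(InvalidInputError):
            subtract_background(stack, roi)

    def test_fish_on_gradient_background_stands_out(self):
        """After subtraction the fish pixels dominate the background."""
        sp = SpineAngleMatrix(dtheta=np.zeros((1, 10)), time_ms=np.array([0.0]))
        from fishposture.synthetic import RenderConfig

        rb = render_fish_frames(sp, RenderConfig(background="gradient"))
        stack = FrameStack(frames=rb.frames, frame_rate=500)
        out = subtract_background(stack, roi_polygon(rb))
        frame = out.frames[0]
        pts = rb.midlines[0]
        r = pts[:, 1].round().astype(int)
        c = pts[:, 0].round().astype(int)
        fish_mean = frame[r, c].mean()
        corners = np.concatenate(
            [frame[:10, :10].ravel(), frame[-10:, -10:].ravel()]
        )
        assert fish_mean >= 10 * corners.mean()


class TestSegmentation:
    def test_straight_rod_path_on_axis(self):
        img, r0 = render_rod()
        path, mask = segment_and_skeletonize(img)
        assert np.abs(path[:, 1] - r0).std() < 1.0
        assert np.sqrt(np.mean((path[:, 1] - r0) ** 2)) < 1.0

    def test_sinusoid_body_followed_within_a_pixel(self):
        size = (140, 160)
        img = np.zeros(size)
        x = np.arange(20, 140)
        y = 70 + 15 * np.sin(2 * np.pi * (x - 20) / 120)
        for xi, yi in zip(x, y):
            img[int(round(yi)) - 2 : int(round(yi)) + 3, xi] = 200.0
        path, _ = segment_and_skeletonize(img)
        interp = np.interp(path[:, 0], x, y)
        core = (path[:, 0] > 25) & (path[:, 0] < 135)
        rms = np.sqrt(np.mean((path[core, 1] - interp[core]) ** 2))
        assert rms < 1.0

    def test_blank_frame_raises(self):
        with pytest.raises(SegmentationError):
            segment_and_skeletonize(np.zeros((50, 50)))

    def test_two_components_is_ambiguous(self):
        img, _ = render_rod()
        img[5:15, 5:15] = 200.0
        with pytest.raises(SegmentationError):
            segment_and_skeletonize(img)


class TestSplineSampling:
    def test_straight_line_sampled_uniformly(self):
        path = np.column_stack([np.arange(10.0), np.zeros(10)])
        pts, ang = fit_spline_sample(path, n=10, smooth=0.0)
        assert np.allclose(pts[:, 0], np.arange(10.0), atol=1e-6)
        assert np.allclose(ang, 0.0, atol=1e-9)

    def test_quarter_circle_chords_equal(self):
        t = np.linspace(0, np.pi / 2, 200)
        path = np.column_stack([50 * np.cos(t), 50 * np.sin(t)])
        pts, _ = fit_spline_sample(path, n=10, smooth=0.0)
        chords = np.hypot(*np.diff(pts, axis=0).T)
        assert chords.std() / chords.mean() < 0.01

    def test_n3_preserves_endpoints(self):
        t = np.linspace(0, 1, 60)
        path = np.column_stack([60 * t, 10 * np.sin(3 * t)])
        pts, _ = fit_spline_sample(path, n=3, smooth=0.0)
        assert np.hypot(*(pts[0] - path[0])) < 1.0
        assert np.hypot(*(pts[-1] - path[-1])) < 1.0

    def test_n_larger_than_path_rejected(self):
        path = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(InvalidInputError):
            fit_spline_sample(path, n=10)


class TestSpineAngles:
    def test_straight_fish_any_heading_is_zero(self):
        for heading in (0.0, 1.1, -2.0):
            d = np.array([np.cos(heading), np.sin(heading)])
            pts = np.outer(np.arange(10.0), d)
            sp = compute_spine_angles(
                [BackboneFrame(points=pts, timestamp_ms=0.0)]
            )
            assert np.allclose(sp.dtheta, 0.0, atol=1e-9)

    def test_circular_arc_matches_closed_form(self):
        phi = 1.0  # arc subtending 1 rad
        s = np.linspace(0, 1, 400)
        R = 1.0 / phi
        pts = np.column_stack([R * np.sin(phi * s), R * (1 - np.cos(phi * s))])
        smp, ang = fit_spline_sample(pts * 100, n=10, smooth=0.0)
        from fishposture.midline import spine_angles_from_tangents

        sp = spine_angles_from_tangents([smp], [ang], np.array([0.0]))
        assert np.allclose(sp.dtheta[0], phi * np.linspace(0, 1, 10), atol=0.01)

    def test_rigid_rotation_leaves_dtheta_unchanged(self):
        rng = np.random.default_rng(0)
        base = np.column_stack([np.linspace(0, 30, 10), 3 * np.sin(np.linspace(0, 2, 10))])
        ang = np.pi / 2
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        a = compute_spine_angles([BackboneFrame(points=base, timestamp_ms=0.0)])
        b = compute_spine_angles(
            [BackboneFrame(points=base @ rot.T + 5.0, timestamp_ms=0.0)]
        )
        assert np.allclose(a.dtheta, b.dtheta, atol=1e-9)
        assert (b.theta_head[0] - a.theta_head[0]) % (2 * np.pi) == pytest.approx(
            np.pi / 2, abs=1e-9
        )

    def test_mixed_point_counts_rejected(self):
        f1 = BackboneFrame(points=np.zeros((10, 2)), timestamp_ms=0.0)
        f2 = BackboneFrame(points=np.zeros((12, 2)), timestamp_ms=2.0)
        with pytest.raises(InvalidInputError):
            compute_spine_angles([f1, f2])


def test_rendered_bout_round_trip(scoot_bout):
    """Full extraction chain recovers the generating spine angles."""
    rb = render_fish_frames(scoot_bout)
    rec = extract_spine(
        FrameStack(frames=rb.frames, frame_rate=500.0), roi_polygon(rb)
    )
    err = rec.dtheta - scoot_bout.dtheta
    assert np.sqrt(np.mean(err**2)) < 0.05
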