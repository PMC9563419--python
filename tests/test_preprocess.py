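import numpy as np
import pytest

from laryngotopo.errors import ConfigurationError, DegenerateInputError, InputError
from laryngotopo.preprocess import (
    FrameOffsets,
    GlottalAxis,
    estimate_offsets,
    extract_channel,
    glare_mask,
    rotate_points,
    rotate_to_vertical,
    select_max_opening_frame,
    stabilize,
    translate_frame,
)
from laryngotopo.video_io import ChannelStack, HSVRecording

from conftest import textured_frame


def _rgb(frames2d):
    """Stack 2-D frames into an all-red RGB recording."""
    frames2d = np.asarray(frames2d)
    rgb = np.zeros(frames2d.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = frames2d
    return HSVRecording(frames=rgb, fps=2400.0)


def _stack(frames2d):
    return ChannelStack(
        frames=np.asarray(frames2d), channel_role="fold_contrast", fps=2400.0
    )


class TestChannelExtraction:
    def test_pure_red_frame_channels(self):
        frames = np.zeros((2, 6, 6, 3), dtype=np.uint8)
        frames[..., 0] = 255
        rec = HSVRecording(frames=frames, fps=2400)
        assert (extract_channel(rec, "fold_contrast").frames == 255).all()
        assert (extract_channel(rec, "glare_reduction").frames == 0).all()

    def test_unknown_role_rejected(self):
        rec = _rgb(np.zeros((2, 6, 6), dtype=np.uint8))
        with pytest.raises(ConfigurationError):
            extract_channel(rec, "green")

    def test_saturated_glare_spot_flagged(self):
        frames = np.zeros((4, 8, 8, 3), dtype=np.uint8)
        frames[:2, 3, 4] = 255  # white in half of the frames -> flagged
        frames[0, 0, 0] = 255  # white in a quarter of the frames -> not
        rec = HSVRecording(frames=frames, fps=2400)
        flagged = glare_mask(rec)
        assert flagged[3, 4]
        assert not flagged[0, 0]
        assert flagged.sum() == 1


def brute_force_shift(ref, mov, radius):
    """Independent oracle: direct NCC of the central template of `mov`
    at every placement in `ref`, full double loop."""
    a, b = ref.astype(float), mov.astype(float)
    h, w = a.shape
    t = b[radius : h - radius, radius : w - radius]
    t = t - t.mean()
    best, arg = -np.inf, (0, 0)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            p = a[radius - dy : h - radius - dy, radius - dx : w - radius - dx]
            pc = p - p.mean()
            den = np.sqrt((pc * pc).sum() * (t * t).sum())
            v = (pc * t).sum() / den if den > 0 else 0.0
            if v > best + 1e-12:
                best, arg = v, (dx, dy)
    return arg


class TestOffsetEstimation:
    def test_planted_single_shift(self, rng):
        f0 = textured_frame(rng)
        f1 = translate_frame(f0, 3, -2)
        off = estimate_offsets(_stack([f0, f1]), search_radius=8)
        assert (off.dx[1], off.dy[1]) == (3, -2)

    def test_identical_frames_give_zero(self, rng):
        f0 = textured_frame(rng)
        off = estimate_offsets(_stack([f0, f0, f0]), search_radius=8)
        assert (off.dx == 0).all() and (off.dy == 0).all()

    def test_cumulative_offsets_accumulate_pairwise_shifts(self, rng):
        """Shifts (2,1) then (-1,0) give cumulative (0,0),(2,1),(1,1),
        cross-checked against a brute-force correlation oracle."""
        f0 = textured_frame(rng)
        f1 = translate_frame(f0, 2, 1)
        f2 = translate_frame(f1, -1, 0)
        off = estimate_offsets(_stack([f0, f1, f2]), search_radius=8)
        assert list(zip(off.dx, off.dy)) == [(0, 0), (2, 1), (1, 1)]
        assert brute_force_shift(f0, f1, 8) == (2, 1)
        assert brute_force_shift(f1, f2, 8) == (-1, 0)

    @pytest.mark.parametrize("shift", [(5, 5), (-8, 3), (0, -7)])
    def test_exact_recovery_of_planted_shifts(self, rng, shift):
        f0 = textured_frame(rng)
        f1 = translate_frame(f0, *shift)
        off = estimate_offsets(_stack([f0, f1]), search_radius=8)
        assert (off.dx[1], off.dy[1]) == shift

    def test_recovery_within_one_pixel_under_noise(self, rng):
        f0 = textured_frame(rng).astype(float)
        f1 = translate_frame(f0, 4, -3)
        noisy = [
            np.clip(f + rng.normal(0, 10, f.shape), 0, 255) for f in (f0, f1)
        ]
        off = estimate_offsets(_stack(noisy), search_radius=8)
        assert abs(off.dx[1] - 4) <= 1 and abs(off.dy[1] + 3) <= 1

    def test_oversized_search_radius_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            estimate_offsets(_stack([textured_frame(rng)] * 2), search_radius=24)


class TestStabilization:
    def test_zero_offsets_identity(self, rng):
        stack = _stack([textured_frame(rng) for _ in range(3)])
        off = FrameOffsets(dx=[0, 0, 0], dy=[0, 0, 0], search_radius=8)
        np.testing.assert_array_equal(stabilize(stack, off).frames, stack.frames)

    def test_translated_pair_realigned_on_overlap(self, rng):
        f0 = textured_frame(rng)
        f1 = translate_frame(f0, 3, 2)
        stack = _stack([f0, f1])
        off = estimate_offsets(stack, search_radius=8)
        out = stabilize(stack, off)
        # overlap excludes the zero-filled 2-row / 3-column borders
        np.testing.assert_array_equal(out.frames[1][:-2, :-3], f0[:-2, :-3])

    def test_stabilized_stack_is_a_fixed_point(self, rng):
        f0 = textured_frame(rng)
        frames = [f0, translate_frame(f0, 4, -1), translate_frame(f0, -2, 3)]
        stack = _stack(frames)
        out = stabilize(stack, estimate_offsets(stack, search_radius=8))
        off2 = estimate_offsets(out, search_radius=8)
        assert (off2.dx == 0).all() and (off2.dy == 0).all()

    def test_frame_zero_offset_must_be_zero(self):
        with pytest.raises(InputError):
            FrameOffsets(dx=[1, 0], dy=[0, 0], search_radius=5)


class TestMaxOpeningFrame:
    @staticmethod
    def _gap_stack(widths, h=40, w=40):
        """Bright frames with a central dark column band of given widths."""
        frames = np.full((len(widths), h, w), 200, dtype=np.uint8)
        for t, gw in enumerate(widths):
            if gw:
                frames[t, 8:32, 20 - gw // 2 : 20 + (gw + 1) // 2] = 5
        return ChannelStack(frames=frames, channel_role="fold_contrast", fps=2400)

    def test_planted_maximum_found(self):
        widths = [4] * 30
        widths[17] = 12
        assert select_max_opening_frame(self._gap_stack(widths)) == 17

    def test_monotone_closing_gap_picks_first_frame(self):
        assert select_max_opening_frame(self._gap_stack([12, 8, 4, 2])) == 0

    def test_tie_resolves_to_smaller_index(self):
        assert select_max_opening_frame(self._gap_stack([4, 10, 6, 10, 4])) == 1

    def test_uniform_stack_rejected(self):
        stack = ChannelStack(
            frames=np.full((4, 20, 20), 99, dtype=np.uint8),
            channel_role="fold_contrast",
            fps=2400,
        )
        with pytest.raises(DegenerateInputError):
            select_max_opening_frame(stack)


class TestAxisRotation:
    def test_axis_angle_conventions(self):
        assert GlottalAxis((10, 2), (10, 30)).angle == 0.0
        assert GlottalAxis((10, 10), (20, 20)).angle == pytest.approx(45.0)
        assert GlottalAxis((20, 20), (10, 10)).angle == pytest.approx(45.0)
        assert GlottalAxis((5, 10), (15, 10)).angle == pytest.approx(90.0)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(InputError):
            GlottalAxis((5, 5), (5, 5))

    def test_vertical_axis_leaves_frames_untouched(self, rng):
        rec = _rgb([textured_frame(rng) for _ in range(2)])
        out, axis = rotate_to_vertical(rec, GlottalAxis((24, 5), (24, 40)))
        np.testing.assert_array_equal(out.frames, rec.frames)
        assert axis.angle == 0.0

    def test_inclined_axis_becomes_vertical(self, rng):
        """45-degree axis: the returned axis is vertical and a bright
        marker on the old axis lands on the new vertical axis (<0.5 px),
        checked against the analytic rotation of the endpoints."""
        h = w = 49
        frames = np.zeros((2, h, w), dtype=np.uint8)
        a, b = (14, 14), (34, 34)
        marker = (30, 30)  # (x, y) on the axis
        frames[:, marker[1], marker[0]] = 255
        rec = _rgb(frames)
        out, axis = rotate_to_vertical(rec, GlottalAxis(a, b))
        assert abs(axis.angle) < 1e-6
        assert axis.endpoint_a[0] == pytest.approx(axis.endpoint_b[0], abs=1e-9)
        # analytic image of the marker under the same rotation
        exp = rotate_points([marker], -45.0, (h, w))[0]
        yy, xx = np.unravel_index(np.argmax(out.frames[0, ..., 0]), (h, w))
        assert np.hypot(xx - exp[0], yy - exp[1]) <= 0.5
        assert abs(exp[0] - axis.endpoint_a[0]) < 1e-9  # marker on the axis

    def test_rotation_round_trip_close_to_identity(self, rng):
        # smooth image: bilinear interpolation error stays sub-intensity
        yy, xx = np.mgrid[0:64, 0:64]
        img = (120 + 60 * np.sin(xx / 6.0) * np.cos(yy / 7.0)).astype(np.uint8)
        rec = _rgb([img, img])
        rot, axis1 = rotate_to_vertical(
            rec, GlottalAxis((20, 16), (30, 48))
        )  # some oblique axis
        angle = GlottalAxis((20, 16), (30, 48)).angle
        # rotate back with an axis inclined the other way
        from laryngotopo.preprocess import rotate_frames

        back = rotate_frames(rot.frames, angle)
        interior = (slice(24, 40), slice(24, 40))
        diff = np.abs(
            back[0][interior].astype(float) - rec.frames[0][interior].astype(float)
        )
        assert diff.mean() < 2.0
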