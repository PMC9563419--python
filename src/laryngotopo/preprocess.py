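"""Pre-processing of laryngeal HSV recordings.

The chain, applied before any spectral analysis:

1. split the RGB recording into its analysis channels — blue flags
   specular glare from the light source, red carries the fold/glottis
   brightness contrast;
2. estimate and remove the whole-frame translation jitter between
   consecutive frames (integer cross-correlation registration);
3. locate the frame with the largest glottic opening (dark-pixel count
   proxy), on which the operator marks the glottal axis;
4. rotate the stack so the glottal axis is vertical.

Every stage is a pure function of its inputs so intermediates can be
cached and tested independently.

Coordinate convention: origin at the top-left pixel, x = column,
y = row; the axis angle is measured from the image vertical,
counterclockwise positive, in degrees, and lies in (-90, 90].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError, InputError
from .video_io import ChannelStack, HSVRecording

__all__ = [
    "FrameOffsets",
    "GlottalAxis",
    "extract_channel",
    "estimate_offsets",
    "stabilize",
    "select_max_opening_frame",
    "rotate_to_vertical",
    "glare_mask",
    "translate_frame",
]

_ROLE_TO_CHANNEL = {"fold_contrast": 0, "glare_reduction": 2}


@dataclass
class FrameOffsets:
    """Integer per-frame displacements relative to frame 0.

    ``dx[t]``/``dy[t]`` say by how many columns/rows the content of
    frame ``t`` is displaced with respect to frame 0 (positive = moved
    right/down).  Frame 0 is (0, 0) by definition.
    """

    dx: np.ndarray
    dy: np.ndarray
    search_radius: int

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=int)
        self.dy = np.asarray(self.dy, dtype=int)
        if self.dx.shape != self.dy.shape or self.dx.ndim != 1:
            raise InputError("dx and dy must be 1-D arrays of equal length")
        if self.dx[0] != 0 or self.dy[0] != 0:
            raise InputError("offset of frame 0 must be (0, 0)")

    def __len__(self) -> int:
        return len(self.dx)


@dataclass
class GlottalAxis:
    """The glottal main axis, marked by two endpoints on the reference
    frame.  ``angle`` is the inclination from the image vertical in
    degrees (counterclockwise positive, in (-90, 90])."""

    endpoint_a: tuple[float, float]
    endpoint_b: tuple[float, float]

    def __post_init__(self) -> None:
        a = (float(self.endpoint_a[0]), float(self.endpoint_a[1]))
        b = (float(self.endpoint_b[0]), float(self.endpoint_b[1]))
        if a == b:
            raise InputError("axis endpoints coincide")
        self.endpoint_a, self.endpoint_b = a, b

    @property
    def angle(self) -> float:
        dx = self.endpoint_b[0] - self.endpoint_a[0]
        dy = self.endpoint_b[1] - self.endpoint_a[1]
        # orient the direction downward so the angle lands in (-90, 90]
        if dy < 0 or (dy == 0 and dx < 0):
            dx, dy = -dx, -dy
        ang = np.degrees(np.arctan2(dx, dy))
        if ang <= -90:  # dy == 0, dx > 0 maps to +90
            ang += 180.0
        return float(ang)

    @property
    def x_mid(self) -> float:
        return 0.5 * (self.endpoint_a[0] + self.endpoint_b[0])


def extract_channel(rec: HSVRecording, role: str) -> ChannelStack:
    """Return one color component of the recording as a channel stack.

    ``fold_contrast`` is the red component (folds vs. glottal gap
    contrast, used for all brightness analysis); ``glare_reduction`` is
    the blue component (specular glare detection).
    """
    if role == "luminance":
        # ITU-R BT.601 luma, occasionally useful for display
        w = np.array([0.299, 0.587, 0.114])
        frames = np.tensordot(rec.frames.astype(np.float64), w, axes=([3], [0]))
        return ChannelStack(frames=frames, channel_role=role, fps=rec.fps)
    if role not in _ROLE_TO_CHANNEL:
        raise ConfigurationError(
            f"unknown channel role {role!r}; expected 'fold_contrast', "
            f"'glare_reduction' or 'luminance'"
        )
    return ChannelStack(
        frames=rec.frames[..., _ROLE_TO_CHANNEL[role]],
        channel_role=role,
        fps=rec.fps,
    )


def glare_mask(
    rec: HSVRecording, saturation: int = 250, min_fraction: float = 0.5
) -> np.ndarray:
    """Boolean H×W mask of glare-contaminated pixels.

    A pixel is flagged when its blue (glare_reduction) component is
    saturated (``>= saturation``) in at least ``min_fraction`` of the
    frames; flagged pixels are excluded from spectral analysis.
    """
    blue = rec.frames[..., 2]
    frac = (blue >= saturation).mean(axis=0)
    return frac >= min_fraction


def translate_frame(frame: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate a frame by integer (dx, dy) = (columns, rows),
    zero-filling vacated borders.  Works for 2-D and 3-D (H, W, C)
    frames."""
    out = np.zeros_like(frame)
    h, w = frame.shape[:2]
    dx, dy = int(dx), int(dy)
    if abs(dx) >= w or abs(dy) >= h:
        return out
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = frame[src_y, src_x]
    return out


def _sliding_sums(a: np.ndarray, th: int, tw: int) -> tuple[np.ndarray, np.ndarray]:
    """Sums and sums of squares of every th×tw patch of ``a``
    (integral-image trick)."""
    def windowed(c: np.ndarray) -> np.ndarray:
        s = np.cumsum(np.cumsum(c, axis=0), axis=1)
        s = np.pad(s, ((1, 0), (1, 0)))
        return s[th:, tw:] - s[:-th, tw:] - s[th:, :-tw] + s[:-th, :-tw]

    return windowed(a), windowed(a * a)


def _pairwise_shift(ref: np.ndarray, mov: np.ndarray, radius: int) -> tuple[int, int]:
    """Integer (dx, dy) within ±radius maximizing the normalized
    cross-correlation between the central template of ``mov`` and the
    correspondingly placed patch of ``ref``.

    The NCC numerator is computed by FFT correlation, the per-placement
    patch statistics by integral images.  Zero shift wins exact ties
    (identical or featureless frames); remaining ties resolve to the
    smallest (dy, dx) in scan order.
    """
    from scipy.signal import fftconvolve

    a = ref.astype(np.float64)
    b = mov.astype(np.float64)
    h, w = a.shape
    t = b[radius : h - radius, radius : w - radius]
    t = t - t.mean()
    t_ss = float((t * t).sum())
    th, tw = t.shape
    # numerator at every placement: sum(patch * t); sum(t) = 0, so the
    # patch mean drops out of the covariance term
    num = fftconvolve(a, t[::-1, ::-1], mode="valid")
    p_sum, p_ss = _sliding_sums(a, th, tw)
    n = th * tw
    p_var = np.maximum(p_ss - p_sum * p_sum / n, 0.0)
    den = np.sqrt(p_var * t_ss)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / den, 0.0)
    # placement (dy, dx) matches mov translated by (-(dy - r), -(dx - r))
    if scores[radius, radius] >= scores.max() - 1e-12:
        return 0, 0
    iy, ix = divmod(int(np.argmax(scores)), scores.shape[1])
    return -(ix - radius), -(iy - radius)


def estimate_offsets(stack: ChannelStack, search_radius: int = 15) -> FrameOffsets:
    """Estimate cumulative integer frame offsets by correlating every
    pair of consecutive frames.

    For each pair, the integer displacement maximizing the
    cross-correlation within ``±search_radius`` pixels is taken; the
    per-frame offsets relative to frame 0 are the cumulative sums.
    """
    h, w = stack.shape
    if search_radius < 1 or search_radius >= min(h, w) / 2:
        raise ConfigurationError(
            f"search_radius {search_radius} must be in [1, min(H, W)/2)"
        )
    if stack.n_frames < 2:
        raise InputError("need at least 2 frames to estimate offsets")
    dx = np.zeros(stack.n_frames, dtype=int)
    dy = np.zeros(stack.n_frames, dtype=int)
    for t in range(1, stack.n_frames):
        sx, sy = _pairwise_shift(stack.frames[t - 1], stack.frames[t], search_radius)
        dx[t] = dx[t - 1] + sx
        dy[t] = dy[t - 1] + sy
    return FrameOffsets(dx=dx, dy=dy, search_radius=search_radius)


def stabilize(rec, offsets: FrameOffsets):
    """Remove inter-frame jitter: translate each frame by the negated
    cumulative offset (zero-filled borders, unchanged dimensions).

    Accepts an :class:`HSVRecording` or a :class:`ChannelStack` and
    returns the same type.
    """
    if len(offsets) != rec.frames.shape[0]:
        raise InputError(
            f"offsets cover {len(offsets)} frames, recording has "
            f"{rec.frames.shape[0]}"
        )
    frames = np.stack(
        [
            translate_frame(rec.frames[t], -offsets.dx[t], -offsets.dy[t])
            for t in range(rec.frames.shape[0])
        ]
    )
    if isinstance(rec, HSVRecording):
        return HSVRecording(frames=frames, fps=rec.fps, source_id=rec.source_id)
    return ChannelStack(frames=frames, channel_role=rec.channel_role, fps=rec.fps)


def select_max_opening_frame(
    stack: ChannelStack,
    dark_quantile: float = 0.25,
    central_fraction: float = 0.5,
) -> int:
    """Index of the frame with the largest glottic opening.

    The opening area is proxied by the number of "dark" pixels —
    intensity strictly below the ``dark_quantile`` quantile of the whole
    stack — inside the central ``central_fraction`` of the image (the
    glottis sits centrally in a usable recording).  Ties resolve to the
    smallest index.
    """
    frames = stack.frames
    if np.ptp(frames) == 0:
        raise DegenerateInputError("uniform stack: no glottic opening detectable")
    thr = np.quantile(frames, dark_quantile)
    h, w = stack.shape
    my = int(round(h * (1 - central_fraction) / 2))
    mx = int(round(w * (1 - central_fraction) / 2))
    central = frames[:, my : h - my, mx : w - mx]
    counts = (central < thr).sum(axis=(1, 2))
    return int(np.argmax(counts))


def _rotation_matrix(angle_deg: float) -> np.ndarray:
    """Point transform matching ``scipy.ndimage.rotate(angle_deg)`` about
    the frame center: ``[dx', dy'] = R @ [dx, dy]``."""
    t = np.radians(angle_deg)
    return np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])


def rotate_points(
    points: np.ndarray, angle_deg: float, shape: tuple[int, int]
) -> np.ndarray:
    """Rotate (x, y) points the way :func:`rotate_frames` rotates image
    content by ``angle_deg`` about the center of a frame of ``shape``."""
    h, w = shape
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return (pts - c) @ _rotation_matrix(angle_deg).T + c


def rotate_frames(frames: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate every frame by ``angle_deg`` about the image center,
    bilinear interpolation, zero fill, dimensions unchanged."""
    out = np.empty_like(frames)
    for t in range(frames.shape[0]):
        out[t] = ndimage.rotate(
            frames[t],
            angle_deg,
            axes=(0, 1),
            reshape=False,
            order=1,
            mode="constant",
            cval=0.0,
        )
    return out


def rotate_to_vertical(rec, axis: GlottalAxis):
    """Rotate the recording so the glottal axis is vertical.

    Every frame is rotated by ``-axis.angle`` about the image center
    (bilinear interpolation, zero-filled corners); the returned axis is
    the rotated one, vertical to numerical precision.  Accepts an
    :class:`HSVRecording` or a :class:`ChannelStack`.
    """
    h, w = rec.frames.shape[1:3]
    for p in (axis.endpoint_a, axis.endpoint_b):
        if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
            raise InputError(f"axis endpoint {p} outside the frame ({h}x{w})")
    angle = axis.angle
    if abs(angle) < 1e-12:
        new_frames = rec.frames.copy()
    else:
        new_frames = rotate_frames(rec.frames, -angle)
    pts = rotate_points(
        np.array([axis.endpoint_a, axis.endpoint_b]), -angle, (h, w)
    )
    # both endpoints now share (numerically) the same x
    new_axis = GlottalAxis(tuple(pts[0]), tuple(pts[1]))
    if isinstance(rec, HSVRecording):
        out = HSVRecording(frames=new_frames, fps=rec.fps, source_id=rec.source_id)
    else:
        out = ChannelStack(
            frames=new_frames, channel_role=rec.channel_role, fps=rec.fps
        )
    return out, new_axis
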