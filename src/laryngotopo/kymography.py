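"""Simplified kymographic glottal-width-waveform (GWW) analysis.

A kymogram watches a single image row over time.  The glottal width at
that row — the length of the dark pixel run between the two folds —
traced over frames gives the GWW, whose spectral peak is an estimate of
the fundamental frequency F0 that is fully independent of the per-pixel
laryngotopographic route.  Its role here is exactly that: an internal
cross-check of the global F0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .roi_geometry import FoldROI
from .spectral_maps import (
    DEFAULT_BAND,
    BrightnessSignal,
    compute_spectrum,
    detect_pixel_f0,
)
from .video_io import ChannelStack

__all__ = ["GWW", "extract_gww", "f0_from_gww"]

#: spectral floor for the width series, in pixels of width modulation
GWW_PEAK_FLOOR = 0.5


@dataclass
class GWW:
    """Glottal width waveform at one kymographic cross-section row."""

    widths: np.ndarray
    row: int
    f0_gww: float | None = None

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(self.widths < 0):
            raise InputError("glottal widths cannot be negative")


def _row_widths(dark: np.ndarray, c0: int) -> np.ndarray:
    """Per-frame length of the contiguous dark run containing column c0."""
    T, w = dark.shape
    widths = np.zeros(T)
    for t in range(T):
        d = dark[t]
        if not d[c0]:
            continue
        lo = c0
        while lo > 0 and d[lo - 1]:
            lo -= 1
        hi = c0
        while hi < w - 1 and d[hi + 1]:
            hi += 1
        widths[t] = hi - lo + 1
    return widths


def extract_gww(
    stack: ChannelStack,
    roi: FoldROI,
    row: int | str = "mid-axis",
    dark_quantile: float = 0.25,
    n_rows: int = 1,
) -> GWW:
    """Extract the glottal width waveform at a cross-section row.

    The glottal width in a frame is the length of the contiguous run of
    "dark" pixels (below the ``dark_quantile`` quantile of the whole
    stack) containing the glottal-axis column; zero when the glottis is
    closed at that row.  ``row='mid-axis'`` uses the row of the ROI
    centroid.  ``n_rows > 1`` averages the widths of that many
    consecutive rows centered on ``row``.
    """
    h, w = stack.shape
    if row == "mid-axis":
        _, cy = roi.centroid
        row = int(round(cy))
    row = int(row)
    if not (0 <= row < h):
        raise InputError(f"row {row} outside the image (H={h})")
    if not roi.roi_mask[row].any():
        raise InputError(f"row {row} does not intersect the ROI")
    if n_rows < 1:
        raise InputError("n_rows must be >= 1")

    thr = np.quantile(stack.frames, dark_quantile)
    c0 = min(max(int(round(roi.axis_x)), 0), w - 1)
    rows = [r for r in range(row - (n_rows - 1) // 2, row + n_rows // 2 + 1)
            if 0 <= r < h and roi.roi_mask[r].any()]
    widths = np.mean(
        [_row_widths(stack.frames[:, r, :] < thr, c0) for r in rows], axis=0
    )
    return GWW(widths=widths, row=row)


def f0_from_gww(
    gww: GWW,
    fps: float,
    band: tuple[float, float] = DEFAULT_BAND,
    peak_floor: float = GWW_PEAK_FLOOR,
) -> float | None:
    """Fundamental frequency of the width series: DC-removed spectral
    peak within the band, or None when no peak exceeds the floor (same
    estimator contract as the per-pixel F0 detection)."""
    if len(gww.widths) < 16:
        raise InputError("need at least 16 width samples")
    spec = compute_spectrum(
        BrightnessSignal(values=gww.widths, fps=fps, pixel=(-1, gww.row))
    )
    f0 = detect_pixel_f0(spec, band=band, peak_floor=peak_floor)
    gww.f0_gww = f0
    return f0
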