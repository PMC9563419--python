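"""Region-of-interest geometry for the vocal folds.

The operator marks up to 20 points along the outer edges of the vocal
folds; a closed third-order (cubic) B-spline through those nodes
delineates the fold region, which is rasterized and split into left and
right fold masks by the (vertical) glottal axis.

The spline is periodic with chord-length parameterization and
*interpolates* the nodes — the curve passes through every marked point,
matching how the contour is drawn on the fold edges.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import splev, splprep

from .errors import InputError

__all__ = ["FoldROI", "fit_bspline_contour", "rasterize_roi", "split_folds"]


@dataclass
class FoldROI:
    """The fold region: marked nodes, dense closed contour, rasterized
    ROI mask and its left/right split at ``axis_x``."""

    nodes: np.ndarray
    contour: np.ndarray
    roi_mask: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    axis_x: float

    @classmethod
    def from_nodes(
        cls,
        nodes,
        shape: tuple[int, int],
        axis_x: float,
        samples_per_segment: int = 20,
    ) -> "FoldROI":
        """Build the full ROI from marked nodes and the axis column."""
        nodes = np.asarray(nodes, dtype=float)
        contour = fit_bspline_contour(nodes, samples_per_segment)
        roi = rasterize_roi(contour, shape)
        left, right = split_folds(roi, axis_x)
        return cls(
            nodes=nodes,
            contour=contour,
            roi_mask=roi,
            left_mask=left,
            right_mask=right,
            axis_x=float(axis_x),
        )

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid of the ROI mask."""
        ys, xs = np.nonzero(self.roi_mask)
        if len(ys) == 0:
            raise InputError("empty ROI")
        return float(xs.mean()), float(ys.mean())


def fit_bspline_contour(nodes, samples_per_segment: int = 20) -> np.ndarray:
    """Fit a closed, interpolating cubic B-spline through ordered nodes.

    Parameters
    ----------
    nodes : (N, 2) array of (x, y), ordered around the region perimeter,
        N >= 4, not all collinear.
    samples_per_segment : dense samples per node-to-node span.

    Returns the densely sampled closed curve as an (M, 2) array whose
    first and last points coincide.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[1] != 2:
        raise InputError(f"nodes must be (N, 2), got {nodes.shape}")
    n = len(nodes)
    if n < 4:
        raise InputError(f"need at least 4 nodes for a cubic B-spline, got {n}")
    if samples_per_segment < 1:
        raise InputError("samples_per_segment must be positive")
    centered = nodes - nodes.mean(axis=0)
    # collinearity: all cross products (relative to the first edge) vanish
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise InputError("nodes are collinear; cannot enclose a region")

    closed = np.vstack([nodes, nodes[:1]])
    chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(chord == 0):
        raise InputError("duplicate consecutive nodes")
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]
    tck, _ = splprep(closed.T, u=u, s=0.0, per=True, k=3)
    uu = np.linspace(0.0, 1.0, n * samples_per_segment + 1)
    x, y = splev(uu, tck)
    curve = np.column_stack([x, y])
    curve[-1] = curve[0]  # exact closure
    return curve


def rasterize_roi(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed curve to a boolean grid.

    A pixel is inside when its center satisfies the even-odd
    (ray-crossing) rule against the polygonal approximation of the
    curve.  Pixel centers lying exactly on a horizontal ray through a
    vertex follow the half-open edge convention standard for scanline
    polygon fills.  Portions of the contour outside the image are
    clipped with a warning.
    """
    contour = np.asarray(contour, dtype=float)
    h, w = shape
    if not np.allclose(contour[0], contour[-1]):
        raise InputError("contour is not closed")
    if (
        contour[:, 0].min() < -0.5
        or contour[:, 0].max() > w - 0.5
        or contour[:, 1].min() < -0.5
        or contour[:, 1].max() > h - 0.5
    ):
        warnings.warn("contour extends outside the image; clipping", stacklevel=2)

    # vectorized even-odd crossing test at all pixel centers
    x0, y0 = contour[:-1, 0], contour[:-1, 1]
    x1, y1 = contour[1:, 0], contour[1:, 1]
    keep = y0 != y1  # horizontal edges never toggle parity
    x0, y0, x1, y1 = x0[keep], y0[keep], x1[keep], y1[keep]
    if len(x0) == 0:
        return np.zeros(shape, dtype=bool)

    ys = np.arange(h, dtype=float)[:, None]  # (H, 1) vs (E,) edges
    straddles = (ys >= np.minimum(y0, y1)) & (ys < np.maximum(y0, y1))
    # x where each edge crosses each scanline
    with np.errstate(divide="ignore", invalid="ignore"):
        xcross = x0 + (ys - y0) * (x1 - x0) / (y1 - y0)
    inside = np.zeros(shape, dtype=bool)
    xs = np.arange(w, dtype=float)
    for row in range(h):
        xc = xcross[row][straddles[row]]
        if len(xc) == 0:
            continue
        # parity of crossings strictly to the right of each pixel center
        inside[row] = (xs[:, None] < xc[None, :]).sum(axis=1) % 2 == 1
    return inside


def split_folds(
    roi_mask: np.ndarray, axis_x: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split the ROI into left and right fold masks at column ``axis_x``.

    Pixel centers with x < axis_x go left, x > axis_x right; centers
    exactly on the axis go left (deterministic tie rule).  The two masks
    always partition the ROI.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    h, w = roi_mask.shape
    ys, xs = np.nonzero(roi_mask)
    if len(xs) and not (xs.min() <= axis_x <= xs.max()):
        warnings.warn(
            f"axis x={axis_x} outside the ROI bounding box "
            f"[{xs.min()}, {xs.max()}]; split still performed",
            stacklevel=2,
        )
    cols = np.arange(w)[None, :]
    left = roi_mask & (cols <= axis_x)
    right = roi_mask & (cols > axis_x)
    return left, right
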