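"""Synthetic HSV scenes with exact ground truth.

The generator renders a desk-scale phantom of a phonating glottis: two
mirrored elliptical folds flanking a dark glottal gap, imaged as an RGB
stack at a laryngoscopic frame rate.  Vibration is modeled as what the
analysis actually observes — per-pixel brightness modulation:

* a *medial vibrating band* in each fold (its area fraction is the one
  knob controlling the expected Stiffness Asymmetry Index) oscillates
  sinusoidally at the common F0, with configurable amplitude and a
  per-fold phase offset;
* the medial edge of each vibrating fold excurses sinusoidally into the
  gap, so the glottal width itself oscillates at F0 (this is what the
  kymographic cross-check measures); the edge pixels that toggle
  between fold and gap brightness belong to that fold's vibrating area;
* the static gap core stays dark, the lateral fold tissue and the
  background stay constant.

Optional nuisances: saturated glare spots, whole-frame translation
jitter (a bounded random walk, like slow camera drift), additive
Gaussian noise, and an inclined glottal axis.

Everything is deterministic given the seed, and the returned
:class:`GroundTruth` carries the masks, F0, phases and the expected SAI
computed from the actual rasterized areas.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigurationError, InputError
from .preprocess import GlottalAxis, rotate_frames, rotate_points, translate_frame
from .video_io import HSVRecording

__all__ = [
    "SyntheticSceneConfig",
    "GroundTruth",
    "generate_recording",
    "generate_cohort",
    "draw_subject_fractions",
    "sample_cohort_sai",
    "GROUP_SAI_BETA",
    "DEFAULT_GROUP_SIZES",
]

#: Beta(a, b) parameters of the per-group SAI distributions, moment-matched
#: to the group means/SDs a clinical cohort of unilateral lesions shows
#: (normophonic 0.10 +/- 0.07, benign 0.16 +/- 0.13, malignant 0.65 +/- 0.18).
GROUP_SAI_BETA: dict[str, tuple[float, float]] = {
    "normophonic": (1.7367, 15.6306),
    "benign": (1.1124, 5.8402),
    "malignant": (3.9140, 2.1076),
}

DEFAULT_GROUP_SIZES: tuple[int, int, int] = (10, 10, 11)


@dataclass
class SyntheticSceneConfig:
    """Full generative description of one synthetic recording."""

    shape: tuple[int, int] = (128, 128)  # (H, W)
    fps: float = 2400.0
    n_frames: int = 480
    f0: float = 150.0  # Hz, common fundamental
    axis_angle: float = 0.0  # glottal-axis inclination from vertical, deg
    fold_halfwidth: int = 22  # ellipse semi-axis along x, px
    fold_halfheight: int = 48  # ellipse semi-axis along y, px
    gap_width: float = 4.0  # static dark gap core width, px
    gap_row_halfheight: int | None = None  # defaults to 0.75 * fold_halfheight
    edge_motion_px: float = 2.0  # medial-edge excursion of a vibrating fold
    vib_frac_left: float = 1.0  # vibrating fraction of the left fold area
    vib_frac_right: float = 1.0
    amp_left: float = 50.0  # brightness modulation amplitude, intensity units
    amp_right: float = 50.0
    phase_left: float = 0.0  # radians
    phase_right: float = 0.0
    baseline: float = 150.0  # fold red-channel brightness
    background: float = 70.0
    gap_dark: float = 10.0
    glare_spots: Sequence[tuple[float, float, float]] = ()  # (x, y, radius)
    jitter: object = None  # None | max magnitude | explicit [(dx, dy), ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if self.n_frames < 2:
            raise ConfigurationError("need at least 2 frames")
        if not (0 < self.f0 < self.fps / 2):
            raise ConfigurationError(
                f"f0={self.f0} must lie below Nyquist ({self.fps / 2} Hz)"
            )
        for frac in (self.vib_frac_left, self.vib_frac_right):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(f"vibrating fraction {frac} outside [0, 1]")
        extent = (
            self.gap_width / 2 + self.edge_motion_px + 2 * self.fold_halfwidth
        )
        if extent >= w / 2 or self.fold_halfheight >= h / 2:
            raise ConfigurationError("fold geometry does not fit inside the frame")

    @property
    def axis_x(self) -> float:
        """Glottal-axis column in the canonical (untilted) frame."""
        return (self.shape[1] - 1) / 2.0


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene."""

    left_mask: np.ndarray
    right_mask: np.ndarray
    vib_left: np.ndarray
    vib_right: np.ndarray
    f0: float
    phase_left: float
    phase_right: float
    expected_sai: float
    affected_side: str
    frac_left: float
    frac_right: float
    axis: GlottalAxis  # in recording coordinates (after any tilt)
    axis_x: float  # canonical vertical-axis column
    nodes: np.ndarray  # landmark nodes in recording coordinates
    jitter_dx: np.ndarray
    jitter_dy: np.ndarray

    def landmarks(self) -> dict:
        """Landmark-file payload (axis endpoints + ROI nodes)."""
        return {
            "axis": [list(self.axis.endpoint_a), list(self.axis.endpoint_b)],
            "reference_frame": "auto",
            "nodes": self.nodes.tolist(),
        }


def _ellipse_mask(shape, cx, cy, a, b):
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def _medial_order(mask: np.ndarray, side: str, cy: float) -> np.ndarray:
    """Flat indices of mask pixels sorted medial-first (toward the gap),
    centrally within a column before the tips; deterministic."""
    ys, xs = np.nonzero(mask)
    key_x = -xs if side == "left" else xs
    order = np.lexsort((ys, np.abs(ys - cy), key_x))
    return np.ravel_multi_index((ys[order], xs[order]), mask.shape)


def _boundary_nodes(union: np.ndarray, n_nodes: int = 16, margin: float = 2.0):
    """Nodes along the outer boundary of the union mask: for evenly
    spaced rays from the centroid, the outermost mask point plus a
    small outward margin."""
    ys, xs = np.nonzero(union)
    c = np.array([xs.mean(), ys.mean()])
    h, w = union.shape
    rmax = float(np.hypot(h, w))
    nodes = []
    for theta in np.linspace(0, 2 * np.pi, n_nodes, endpoint=False):
        d = np.array([np.cos(theta), np.sin(theta)])
        hit = None
        for r in np.arange(rmax, 0.0, -0.5):
            p = c + r * d
            xi, yi = int(round(p[0])), int(round(p[1]))
            if 0 <= xi < w and 0 <= yi < h and union[yi, xi]:
                hit = r
                break
        if hit is None:
            continue
        p = c + (hit + margin) * d
        nodes.append([min(max(p[0], 0.0), w - 1.0), min(max(p[1], 0.0), h - 1.0)])
    return np.asarray(nodes)


def _jitter_sequence(cfg: SyntheticSceneConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    T = cfg.n_frames
    if cfg.jitter is None:
        return np.zeros(T, dtype=int), np.zeros(T, dtype=int)
    if np.isscalar(cfg.jitter):
        mag = int(cfg.jitter)
        if mag == 0:
            return np.zeros(T, dtype=int), np.zeros(T, dtype=int)
        step = min(3, mag)
        # bounded random walk: consecutive-frame displacement stays small,
        # cumulative drift stays within +/- mag, frame 0 at (0, 0)
        sx = rng.integers(-step, step + 1, size=T)
        sy = rng.integers(-step, step + 1, size=T)
        sx[0] = sy[0] = 0
        dx = np.clip(np.cumsum(sx), -mag, mag)
        dy = np.clip(np.cumsum(sy), -mag, mag)
        dx -= dx[0]
        dy -= dy[0]
        return dx.astype(int), dy.astype(int)
    seq = np.asarray(cfg.jitter, dtype=int)
    if seq.shape != (T, 2):
        raise ConfigurationError(
            f"explicit jitter must be (T, 2) = ({T}, 2), got {seq.shape}"
        )
    if seq[0, 0] != 0 or seq[0, 1] != 0:
        raise ConfigurationError("jitter of frame 0 must be (0, 0)")
    return seq[:, 0].copy(), seq[:, 1].copy()


def generate_recording(
    cfg: SyntheticSceneConfig,
) -> tuple[HSVRecording, GroundTruth]:
    """Render a synthetic recording and its ground truth."""
    h, w = cfg.shape
    cy = (h - 1) / 2.0
    ax = cfg.axis_x
    b_gap = (
        int(round(0.75 * cfg.fold_halfheight))
        if cfg.gap_row_halfheight is None
        else int(cfg.gap_row_halfheight)
    )
    rng = np.random.default_rng(cfg.seed)
    y, x = np.mgrid[0:h, 0:w]
    gap_rows = np.abs(y - cy) <= b_gap

    half_gap = cfg.gap_width / 2.0
    gap_core = gap_rows & (np.abs(x - ax) <= half_gap)

    sides = {}
    for side, frac, amp, phase in (
        ("left", cfg.vib_frac_left, cfg.amp_left, cfg.phase_left),
        ("right", cfg.vib_frac_right, cfg.amp_right, cfg.phase_right),
    ):
        e = cfg.edge_motion_px if (frac > 0 and amp > 0) else 0.0
        sgn = -1.0 if side == "left" else 1.0
        edge = ax + sgn * half_gap  # static gap-core edge on this side
        # toggle zone: pixels the moving medial edge alternately covers
        depth = sgn * (x - edge)  # distance into the fold from the edge
        toggle = gap_rows & (depth > 0) & (depth <= e)
        ell_cx = ax + sgn * (half_gap + e + cfg.fold_halfwidth)
        ellipse = _ellipse_mask(
            (h, w), ell_cx, cy, cfg.fold_halfwidth, cfg.fold_halfheight
        ) & ~toggle
        fold = ellipse | toggle
        area = int(fold.sum())
        target = int(round(frac * area))
        n_extra = max(0, target - int(toggle.sum()))
        vib = toggle.copy()
        if n_extra:
            flat = _medial_order(ellipse, side, cy)[:n_extra]
            vib.flat[flat] = True
        sides[side] = dict(
            fold=fold,
            vib=vib,
            toggle=toggle,
            depth=depth,
            e=e,
            amp=amp,
            phase=phase,
            frac=(vib.sum() / area) if area else 0.0,
        )
        if area == 0:
            raise ConfigurationError("degenerate geometry: empty fold mask")

    # static base image (red channel)
    red0 = np.full((h, w), cfg.background)
    for s in sides.values():
        red0[s["fold"]] = cfg.baseline
    red0[gap_core] = cfg.gap_dark

    glare = np.zeros((h, w), dtype=bool)
    for gx, gy, gr in cfg.glare_spots:
        glare |= (x - gx) ** 2 + (y - gy) ** 2 <= gr**2

    jdx, jdy = _jitter_sequence(cfg, rng)
    t = np.arange(cfg.n_frames)
    omega = 2 * np.pi * cfg.f0 * t / cfg.fps

    frames = np.empty((cfg.n_frames, h, w, 3), dtype=np.uint8)
    tilt = float(cfg.axis_angle)
    for k in range(cfg.n_frames):
        red = red0.copy()
        for s in sides.values():
            ph = omega[k] + s["phase"]
            mod = s["vib"] & ~s["toggle"]
            red[mod] = cfg.baseline + s["amp"] * np.sin(ph)
            if s["e"] > 0:
                open_level = 0.5 + 0.5 * np.sin(ph)
                covered = s["toggle"] & (s["depth"] <= s["e"] * open_level)
                red[covered] = cfg.gap_dark
        rgb = np.empty((h, w, 3))
        rgb[..., 0] = red
        rgb[..., 1] = 0.4 * red
        rgb[..., 2] = 30.0
        rgb[glare] = 255.0
        if tilt != 0.0:
            rgb = rotate_frames(rgb[None], tilt)[0]
        if jdx[k] or jdy[k]:
            rgb = translate_frame(rgb, jdx[k], jdy[k])
        if cfg.noise_sd > 0:
            rgb = rgb + rng.normal(0.0, cfg.noise_sd, rgb.shape)
        frames[k] = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    # ground-truth bookkeeping (canonical, untilted coordinates)
    fl, fr = sides["left"]["frac"], sides["right"]["frac"]
    affected = "left" if fl <= fr else "right"
    lo, hi = (fl, fr) if affected == "left" else (fr, fl)
    expected_sai = 1.0 - (lo / hi) if hi > 0 else float("nan")

    union = sides["left"]["fold"] | sides["right"]["fold"] | gap_core
    nodes = _boundary_nodes(union)
    axis_pts = np.array([[ax, cy - cfg.fold_halfheight], [ax, cy + cfg.fold_halfheight]])
    if tilt != 0.0:
        axis_pts = rotate_points(axis_pts, tilt, (h, w))
        nodes = rotate_points(nodes, tilt, (h, w))
    gt = GroundTruth(
        left_mask=sides["left"]["fold"],
        right_mask=sides["right"]["fold"],
        vib_left=sides["left"]["vib"],
        vib_right=sides["right"]["vib"],
        f0=cfg.f0,
        phase_left=cfg.phase_left,
        phase_right=cfg.phase_right,
        expected_sai=expected_sai,
        affected_side=affected,
        frac_left=fl,
        frac_right=fr,
        axis=GlottalAxis(tuple(axis_pts[0]), tuple(axis_pts[1])),
        axis_x=ax,
        nodes=nodes,
        jitter_dx=jdx,
        jitter_dy=jdy,
    )
    rec = HSVRecording(
        frames=frames, fps=cfg.fps, source_id=f"synthetic(seed={cfg.seed})"
    )
    return rec, gt


# ---------------------------------------------------------------------------
# cohorts

def draw_subject_fractions(
    group: str, rng: np.random.Generator
) -> tuple[float, float, str]:
    """Draw one subject: (affected fraction, non-affected fraction,
    affected side).

    The target SAI is drawn from the group's Beta distribution
    (:data:`GROUP_SAI_BETA`); the non-affected fold vibrates nearly
    fully (uniform 0.85–1.0) and the affected fraction follows from the
    SAI definition, so the subject's expected SAI equals the draw.
    """
    if group not in GROUP_SAI_BETA:
        raise ConfigurationError(
            f"unknown group {group!r}; expected one of {list(GROUP_SAI_BETA)}"
        )
    a, b = GROUP_SAI_BETA[group]
    s = float(rng.beta(a, b))
    frac_n = float(rng.uniform(0.85, 1.0))
    frac_a = frac_n * (1.0 - s)
    side = str(rng.choice(["left", "right"]))
    return frac_a, frac_n, side


def generate_cohort(
    n_per_group: Sequence[int] = DEFAULT_GROUP_SIZES,
    seed: int = 0,
    groups: Sequence[str] = ("normophonic", "benign", "malignant"),
    base_cfg: SyntheticSceneConfig | None = None,
) -> Iterator[tuple[HSVRecording, GroundTruth, str]]:
    """Yield (recording, ground truth, group label) for a reproducible
    synthetic cohort.

    Group sizes default to a 10/10/11 normophonic/benign/malignant
    design.  Recordings are yielded lazily (each desk-scale recording is
    tens of MB).  ``base_cfg`` supplies all scene parameters other than
    the per-subject vibrating fractions and seed.
    """
    if len(n_per_group) != len(groups):
        raise InputError("n_per_group and groups must align")
    if any(n < 1 for n in n_per_group):
        raise InputError("every group needs at least 1 subject")
    base = base_cfg or SyntheticSceneConfig()
    rng = np.random.default_rng(seed)
    for group, n in zip(groups, n_per_group):
        for _ in range(n):
            frac_a, frac_n, side = draw_subject_fractions(group, rng)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            kw = asdict(base)
            kw.update(
                vib_frac_left=frac_a if side == "left" else frac_n,
                vib_frac_right=frac_a if side == "right" else frac_n,
                seed=sub_seed,
            )
            cfg = SyntheticSceneConfig(**kw)
            rec, gt = generate_recording(cfg)
            yield rec, gt, group


def sample_cohort_sai(
    n_per_group: Sequence[int] = DEFAULT_GROUP_SIZES,
    seed: int = 0,
    groups: Sequence[str] = ("normophonic", "benign", "malignant"),
    fold_shape: tuple[int, int] = (48, 24),
) -> dict[str, list[float]]:
    """Per-group SAI samples from mask-level scenes.

    Draws the same per-subject vibrating fractions as
    :func:`generate_cohort` but realizes them directly as rectangular
    fold masks and computes SAI through :func:`~laryngotopo.sai_metrics.compute_sai`
    — the fast route for statistical (many-replicate) studies where
    rendering full video stacks adds nothing.
    """
    from .sai_metrics import compute_sai

    fh, fw = fold_shape
    h, w = fh, 2 * fw + 2
    rng = np.random.default_rng(seed)
    left = np.zeros((h, w), dtype=bool)
    right = np.zeros((h, w), dtype=bool)
    left[:, :fw] = True
    right[:, fw + 2 :] = True
    # medial-first fill order: left fold fills from its right edge inward
    left_order = np.ravel_multi_index(
        np.nonzero(left), (h, w)
    )[np.lexsort((np.nonzero(left)[0], -np.nonzero(left)[1]))]
    right_order = np.ravel_multi_index(
        np.nonzero(right), (h, w)
    )[np.lexsort((np.nonzero(right)[0], np.nonzero(right)[1]))]
    area = fh * fw

    out: dict[str, list[float]] = {g: [] for g in groups}
    for group, n in zip(groups, n_per_group):
        for _ in range(n):
            frac_a, frac_n, side = draw_subject_fractions(group, rng)
            frac_l, frac_r = (
                (frac_a, frac_n) if side == "left" else (frac_n, frac_a)
            )
            vib = np.zeros((h, w), dtype=bool)
            vib.flat[left_order[: int(round(frac_l * area))]] = True
            vib.flat[right_order[: int(round(frac_r * area))]] = True
            res = compute_sai(left, right, vib, affected_side="auto")
            out[group].append(res.sai)
    return out
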