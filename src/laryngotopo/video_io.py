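"""Reading and writing of high-speed videolaryngoscopy (HSV) recordings.

An HSV recording is an ordered stack of RGB frames captured at a known,
high frame rate (typically 2400 or 3200 fps).  Two on-disk dialects are
supported:

* a directory of lexicographically ordered, losslessly compressed frame
  images (PNG/TIFF), optionally with a ``recording.json`` sidecar holding
  the frame rate — the reference dialect, bit-exact and codec-free;
* any video container that imageio can decode (AVI/MP4, ...).  Lossy
  codecs perturb per-pixel spectra, so frame directories are preferred
  for quantitative work.

This module isolates every container/codec concern from the numerical
pipeline; everything downstream operates on in-memory arrays.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, InputError

__all__ = [
    "HSVRecording",
    "ChannelStack",
    "read_recording",
    "write_recording",
    "write_maps",
]

#: glob used to locate frame files inside a frame directory.  Frames are
#: sorted lexicographically, so numbering must be zero-padded
#: (``frame_000017.png``).
FRAME_GLOB = "*.png"

_CHANNEL_ROLES = ("glare_reduction", "fold_contrast", "luminance")


@dataclass
class HSVRecording:
    """An ordered RGB frame stack with its frame rate.

    ``frames`` has shape ``(T, H, W, 3)`` with integer intensities in
    [0, 255]; ``fps`` is the capture rate in frames per second.
    """

    frames: np.ndarray
    fps: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise InputError(
                f"expected frames of shape (T, H, W, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InputError("a recording needs at least 2 frames")
        if self.frames.dtype != np.uint8:
            lo, hi = self.frames.min(), self.frames.max()
            if lo < 0 or hi > 255:
                raise InputError(f"intensities outside [0, 255]: [{lo}, {hi}]")
            self.frames = self.frames.astype(np.uint8)
        if not self.fps or self.fps <= 0:
            raise ConfigurationError(f"frame rate must be positive, got {self.fps}")
        self.fps = float(self.fps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:3]


@dataclass
class ChannelStack:
    """A single-channel view of a recording (same T, H, W).

    ``channel_role`` records which color component the stack carries:
    ``glare_reduction`` (blue, used to flag specular reflections),
    ``fold_contrast`` (red, used for all brightness analysis) or
    ``luminance``.
    """

    frames: np.ndarray
    channel_role: str
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InputError(
                f"expected frames of shape (T, H, W), got {self.frames.shape}"
            )
        if self.channel_role not in _CHANNEL_ROLES:
            raise ConfigurationError(
                f"unknown channel role {self.channel_role!r}; "
                f"expected one of {_CHANNEL_ROLES}"
            )
        self.fps = float(self.fps)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


def _read_frame_dir(path: Path, pattern: str) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(path.glob(pattern))
    if not files:
        raise InputError(f"no frames matching {pattern!r} in {path}")
    frames = []
    shape = None
    for f in files:
        try:
            img = iio.imread(f)
        except Exception as exc:  # pragma: no cover - imageio specifics
            raise FormatError(f"cannot decode frame {f}: {exc}") from exc
        if img.ndim == 2:  # grayscale frame: replicate to RGB
            img = np.repeat(img[:, :, None], 3, axis=2)
        if img.shape[-1] == 4:  # drop alpha
            img = img[..., :3]
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise InputError(
                f"frame size mismatch: {f.name} is {img.shape[:2]}, "
                f"expected {shape[:2]}"
            )
        frames.append(img)
    return np.stack(frames)


def _read_video_file(path: Path) -> tuple[np.ndarray, float | None]:
    import imageio.v3 as iio

    try:
        frames = iio.imread(path, index=None)
    except Exception as exc:
        raise FormatError(f"cannot decode video {path}: {exc}") from exc
    fps = None
    try:
        meta = iio.immeta(path)
        fps = float(meta.get("fps")) if meta.get("fps") else None
    except Exception:
        pass
    frames = np.asarray(frames)
    if frames.ndim == 3:  # grayscale video
        frames = np.repeat(frames[..., None], 3, axis=3)
    if frames.shape[-1] == 4:
        frames = frames[..., :3]
    return frames, fps


def read_recording(
    path: str | Path,
    fps_override: float | None = None,
    pattern: str = FRAME_GLOB,
) -> HSVRecording:
    """Read an HSV recording from a video file or a frame directory.

    Frames in a directory are matched by ``pattern`` and sorted
    lexicographically; a ``recording.json`` sidecar, when present,
    supplies the frame rate.  ``fps_override`` always wins.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")
    fps = fps_override
    if path.is_dir():
        frames = _read_frame_dir(path, pattern)
        sidecar = path / "recording.json"
        if fps is None and sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fps = meta.get("fps")
        source_id = path.name
    else:
        frames, meta_fps = _read_video_file(path)
        if fps is None:
            fps = meta_fps
        source_id = path.name
    if fps is None:
        raise ConfigurationError(
            f"frame rate unavailable for {path}; pass fps_override"
        )
    if frames.shape[0] < 2:
        raise InputError(f"recording {path} has fewer than 2 frames")
    return HSVRecording(frames=frames, fps=float(fps), source_id=source_id)


def write_recording(rec: HSVRecording, out_dir: str | Path) -> list[Path]:
    """Write a recording as a zero-padded PNG frame directory.

    A ``recording.json`` sidecar stores the frame rate and provenance so
    the directory round-trips through :func:`read_recording` without an
    fps override.  Returns the list of files written.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in range(rec.n_frames):
        f = out_dir / f"frame_{t:06d}.png"
        iio.imwrite(f, rec.frames[t])
        written.append(f)
    sidecar = out_dir / "recording.json"
    sidecar.write_text(
        json.dumps({"fps": rec.fps, "source_id": rec.source_id, "n_frames": rec.n_frames})
    )
    written.append(sidecar)
    return written


# ---------------------------------------------------------------------------
# map export

def _write_grid_csv(grid: np.ndarray, path: Path) -> None:
    # row-major, origin top-left, no header; NaN marks pixels with no value
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",", fmt="%.10g")


def _write_map_png(grid: np.ndarray, path: Path, cmap: str, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    masked = np.ma.masked_invalid(np.asarray(grid, dtype=float))
    im = ax.imshow(masked, cmap=cmap, origin="upper", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.85)
    ax.set_title(title)
    ax.set_xlabel("x [px]")
    ax.set_ylabel("y [px]")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def write_maps(maps, out_dir: str | Path, formats: set[str] = frozenset({"csv", "png"})):
    """Export laryngotopographic maps as pseudocolor PNGs, plain-text CSV
    grids and/or a compressed array container.

    Phase is written in radians; grids are row-major with the origin at
    the image's top-left pixel.  Returns the manifest of written files
    (also saved as ``manifest.json``).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise FormatError(f"output directory not writable: {out_dir}: {exc}") from exc

    manifest: list[str] = []
    grids = {
        "f0_map": (maps.f0_map, "viridis", "pixel F0 [Hz]"),
        "amplitude_map": (maps.amp_map, "inferno", "normalized amplitude at F0"),
        "phase_map": (maps.phase_map, "twilight", "phase at F0 [rad]"),
        "vibrating_mask": (
            maps.vibrating_mask.astype(float),
            "gray",
            f"vibrating mask (amp >= {maps.amp_threshold})",
        ),
    }
    if "csv" in formats:
        for name, (grid, _, _) in grids.items():
            p = out_dir / f"{name}.csv"
            _write_grid_csv(grid, p)
            manifest.append(str(p))
    if "png" in formats:
        for name, (grid, cmap, title) in grids.items():
            p = out_dir / f"{name}.png"
            _write_map_png(grid, p, cmap, title)
            manifest.append(str(p))
    if "npz" in formats:
        p = out_dir / "maps.npz"
        np.savez_compressed(
            p,
            f0_map=maps.f0_map,
            amp_map=maps.amp_map,
            phase_map=maps.phase_map,
            vibrating_mask=maps.vibrating_mask,
            global_f0=maps.global_f0,
            amp_threshold=maps.amp_threshold,
        )
        manifest.append(str(p))
    if manifest:
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1))
    return manifest
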