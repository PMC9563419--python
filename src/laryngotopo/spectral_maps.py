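"""Per-pixel spectral analysis and laryngotopographic (LTG) maps.

For every pixel inside the fold ROI, the time series of its red-channel
intensity — the *brightness function*, values 0–255 — is transformed
with a discrete Fourier transform after per-pixel mean (DC) removal.
One-sided amplitudes are scaled by 2/T so a unit-amplitude sinusoid at a
bin center reads as amplitude 1.  Three maps result:

* the F0 map: each pixel's own spectral peak frequency inside the
  analysis band (or none when the peak is below an absolute floor);
* the amplitude map: the amplitude at the bin nearest the *global*
  fundamental frequency, normalized by the maximum over all analyzed
  pixels (so the map maximum is exactly 1);
* the phase map: the phase at the same bin, radians in (-pi, pi].

Pixels whose normalized amplitude reaches ``amp_threshold`` (default
0.1) and that are not glare-flagged form the *vibrating mask* — the set
of fold pixels showing clear harmonic oscillation at F0.

The global F0 is the amplitude-weighted mode of the per-pixel peak
frequencies over the ROI; an independent estimate from kymography (see
:mod:`laryngotopo.kymography`) serves as its cross-check.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, InputError
from .roi_geometry import FoldROI
from .video_io import ChannelStack

__all__ = [
    "BrightnessSignal",
    "PixelSpectrum",
    "LTGMaps",
    "pixel_brightness_series",
    "compute_spectrum",
    "detect_pixel_f0",
    "estimate_global_f0",
    "build_ltg_maps",
    "DEFAULT_BAND",
    "DEFAULT_AMP_THRESHOLD",
    "DEFAULT_PEAK_FLOOR",
]

#: analysis band in Hz; generously covers phonation F0 (90–370 Hz observed)
DEFAULT_BAND: tuple[float, float] = (70.0, 400.0)
#: normalized-amplitude cutoff for the vibrating mask
DEFAULT_AMP_THRESHOLD: float = 0.1
#: absolute amplitude (intensity units) below which no harmonic is declared
DEFAULT_PEAK_FLOOR: float = 1.0


@dataclass
class BrightnessSignal:
    """Brightness time series of a single pixel."""

    values: np.ndarray
    fps: float
    pixel: tuple[int, int]  # (x, y)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("brightness signal must be 1-D")


@dataclass
class PixelSpectrum:
    """One-sided DFT of a brightness signal: frequencies ``k * fps / T``,
    amplitudes (2/T scaling) and phases in (-pi, pi]."""

    freqs: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.freqs) == len(self.amplitudes) == len(self.phases)):
            raise InputError("freqs, amplitudes and phases must align")


@dataclass
class LTGMaps:
    """The laryngotopographic maps (NaN outside the analyzed region)."""

    f0_map: np.ndarray
    amp_map: np.ndarray
    phase_map: np.ndarray
    vibrating_mask: np.ndarray
    global_f0: float
    amp_threshold: float = DEFAULT_AMP_THRESHOLD


def pixel_brightness_series(stack: ChannelStack, pixel: tuple[int, int]) -> BrightnessSignal:
    """The untransformed brightness function of one pixel, (x, y)."""
    x, y = int(pixel[0]), int(pixel[1])
    h, w = stack.shape
    if not (0 <= x < w and 0 <= y < h):
        raise InputError(f"pixel ({x}, {y}) outside the {h}x{w} image")
    return BrightnessSignal(
        values=stack.frames[:, y, x].astype(float), fps=stack.fps, pixel=(x, y)
    )


def _window(T: int, kind: str) -> np.ndarray:
    if kind in (None, "none"):
        return np.ones(T)
    if kind == "hann":
        return np.hanning(T)
    raise ConfigurationError(f"unknown window {kind!r}; use 'none' or 'hann'")


def compute_spectrum(sig: BrightnessSignal, window: str = "none") -> PixelSpectrum:
    """One-sided DFT of a brightness signal, DC removed.

    Amplitudes are scaled by ``2 / sum(w)`` (``2/T`` for the default
    rectangular window) so a sinusoid of amplitude A at a bin center
    yields a spectral amplitude of A.
    """
    v = np.asarray(sig.values, dtype=float)
    T = len(v)
    if T < 16:
        raise InputError(f"need at least 16 samples for a spectrum, got {T}")
    w = _window(T, window)
    X = np.fft.rfft((v - v.mean()) * w)
    scale = 2.0 / w.sum()
    amps = np.abs(X) * scale
    amps[0] *= 0.5  # the DC bin is not doubled (it is ~0 after mean removal)
    return PixelSpectrum(
        freqs=np.fft.rfftfreq(T, d=1.0 / sig.fps),
        amplitudes=amps,
        phases=np.angle(X),
    )


def _band_slice(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if hi <= lo:
        raise ConfigurationError(f"empty frequency band {band}")
    idx = np.nonzero((freqs >= lo) & (freqs <= hi))[0]
    if len(idx) == 0:
        raise ConfigurationError(f"band {band} contains no frequency bin")
    return idx


def detect_pixel_f0(
    spec: PixelSpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
    peak_floor: float = DEFAULT_PEAK_FLOOR,
) -> float | None:
    """Frequency of the maximal amplitude bin within the band, or None
    when that maximum stays below ``peak_floor`` (no harmonic — the
    pixel does not oscillate)."""
    idx = _band_slice(spec.freqs, band)
    k = idx[int(np.argmax(spec.amplitudes[idx]))]
    if spec.amplitudes[k] < peak_floor:
        return None
    return float(spec.freqs[k])


def _roi_spectra(
    stack: ChannelStack, mask: np.ndarray, window: str = "none"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized spectra of every mask pixel.

    Returns (freqs (K,), amplitudes (K, N), phases (K, N)) with N mask
    pixels in ``np.nonzero`` order.
    """
    T = stack.n_frames
    if T < 16:
        raise InputError(f"need at least 16 frames, got {T}")
    sig = stack.frames[:, mask].astype(np.float64)  # (T, N)
    sig -= sig.mean(axis=0, keepdims=True)
    w = _window(T, window)
    X = np.fft.rfft(sig * w[:, None], axis=0)
    scale = 2.0 / w.sum()
    amps = np.abs(X) * scale
    amps[0] *= 0.5
    return np.fft.rfftfreq(T, d=1.0 / stack.fps), amps, np.angle(X)


def estimate_global_f0(
    stack: ChannelStack,
    roi: FoldROI | np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    peak_floor: float = DEFAULT_PEAK_FLOOR,
    window: str = "none",
) -> float:
    """Global fundamental frequency over the ROI.

    Each ROI pixel votes for its spectral peak bin with a weight equal
    to the peak amplitude; the returned F0 is the highest-weight bin
    (amplitude-weighted mode at the FFT bin resolution).  Deterministic:
    ties resolve to the lowest frequency.
    """
    mask = roi.roi_mask if isinstance(roi, FoldROI) else np.asarray(roi, dtype=bool)
    if not mask.any():
        raise InputError("empty ROI")
    freqs, amps, _ = _roi_spectra(stack, mask, window)
    idx = _band_slice(freqs, band)
    sub = amps[idx]  # (B, N)
    peak_pos = np.argmax(sub, axis=0)  # per-pixel peak bin within band
    peak_amp = sub[peak_pos, np.arange(sub.shape[1])]
    valid = peak_amp >= peak_floor
    if not valid.any():
        raise DegenerateInputError(
            "no ROI pixel carries a spectral peak above the floor"
        )
    votes = np.bincount(
        peak_pos[valid], weights=peak_amp[valid], minlength=len(idx)
    )
    return float(freqs[idx[int(np.argmax(votes))]])


def build_ltg_maps(
    stack: ChannelStack,
    roi: FoldROI | np.ndarray,
    global_f0: float,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    band: tuple[float, float] = DEFAULT_BAND,
    peak_floor: float = DEFAULT_PEAK_FLOOR,
    glare: np.ndarray | None = None,
    window: str = "none",
    strict_f0: bool = False,
) -> LTGMaps:
    """Build the F0 / amplitude / phase maps and the vibrating mask.

    For each analyzed pixel (ROI minus glare-flagged pixels) the
    amplitude and phase are read at the FFT bin nearest ``global_f0``;
    amplitudes are normalized by their maximum over analyzed pixels.
    The vibrating mask collects pixels whose normalized amplitude
    reaches ``amp_threshold``; with ``strict_f0`` the pixel's own
    spectral peak must additionally lie within one bin of the global
    F0.
    """
    if not (0.0 < amp_threshold < 1.0):
        raise ConfigurationError(f"amp_threshold must be in (0, 1), got {amp_threshold}")
    mask = roi.roi_mask if isinstance(roi, FoldROI) else np.asarray(roi, dtype=bool)
    analyzed = mask if glare is None else (mask & ~np.asarray(glare, dtype=bool))
    if not analyzed.any():
        raise InputError("no analyzable pixel (ROI empty or fully glare-flagged)")
    freqs, amps, phases = _roi_spectra(stack, analyzed, window)
    band_idx = _band_slice(freqs, band)
    if not (freqs[band_idx[0]] <= global_f0 <= freqs[band_idx[-1]]):
        raise ConfigurationError(
            f"global F0 {global_f0} Hz outside the analysis band {band}"
        )
    k0 = int(np.argmin(np.abs(freqs - global_f0)))
    amp_at_f0 = amps[k0]
    phase_at_f0 = phases[k0]
    amax = amp_at_f0.max()
    if amax <= 0:
        raise DegenerateInputError("all amplitudes at the F0 bin are zero")
    norm_amp = amp_at_f0 / amax

    # per-pixel own peak frequency (NaN when below the floor)
    sub = amps[band_idx]
    peak_pos = np.argmax(sub, axis=0)
    peak_amp = sub[peak_pos, np.arange(sub.shape[1])]
    pix_f0 = freqs[band_idx[peak_pos]].astype(float)
    pix_f0[peak_amp < peak_floor] = np.nan

    h, w = stack.shape
    f0_map = np.full((h, w), np.nan)
    amp_map = np.full((h, w), np.nan)
    phase_map = np.full((h, w), np.nan)
    f0_map[analyzed] = pix_f0
    amp_map[analyzed] = norm_amp
    phase_map[analyzed] = phase_at_f0
    vibrating = np.zeros((h, w), dtype=bool)
    vib_flat = norm_amp >= amp_threshold
    if strict_f0:
        bin_hz = stack.fps / stack.n_frames
        with np.errstate(invalid="ignore"):
            vib_flat &= np.abs(pix_f0 - global_f0) <= bin_hz + 1e-9
        vib_flat &= ~np.isnan(pix_f0)
    vibrating[analyzed] = vib_flat
    return LTGMaps(
        f0_map=f0_map,
        amp_map=amp_map,
        phase_map=phase_map,
        vibrating_mask=vibrating,
        global_f0=float(global_f0),
        amp_threshold=float(amp_threshold),
    )
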