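"""End-to-end orchestration of a laryngotopographic run.

A single run executes, in order: read recording → channel extraction →
inter-frame offset estimation and stabilization → maximum-opening frame
selection → rotation to a vertical glottal axis → B-spline ROI and
left/right fold split → per-pixel spectra and global F0 → LTG maps →
Stiffness Asymmetry Index → kymographic (GWW) F0 cross-check → exports.

A cohort run repeats this per recording and adds group summaries with
pairwise Mann-Whitney tests and a box plot.

The interactive steps of a clinical workflow (axis marking, node
placement) are replaced by a landmark file for batch reproducibility::

    {"axis": [[x, y], [x, y]], "reference_frame": "auto",
     "nodes": [[x, y], ...]}
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import kymography, preprocess, roi_geometry, sai_metrics, spectral_maps, video_io
from .errors import ConfigurationError, InputError
from .preprocess import GlottalAxis
from .video_io import HSVRecording

__all__ = ["RunConfig", "RunResult", "run_single", "run_on_recording", "run_cohort", "load_landmarks"]

log = logging.getLogger("laryngotopo")


@dataclass
class RunConfig:
    """Configuration of a single laryngotopographic run."""

    input_path: str | Path | None = None
    landmarks: str | Path | dict | None = None
    fps: float | None = None
    affected_side: str = "auto"
    band: tuple[float, float] = spectral_maps.DEFAULT_BAND
    amp_threshold: float = spectral_maps.DEFAULT_AMP_THRESHOLD
    peak_floor: float = spectral_maps.DEFAULT_PEAK_FLOOR
    window: str = "none"
    search_radius: int = 15
    dark_quantile: float = 0.25
    out_dir: str | Path | None = None
    export_formats: tuple[str, ...] = ("csv", "png")
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.amp_threshold < 1.0):
            raise ConfigurationError(
                f"amp_threshold must be in (0, 1), got {self.amp_threshold}"
            )
        lo, hi = self.band
        if hi <= lo or lo < 0:
            raise ConfigurationError(f"invalid frequency band {self.band}")


@dataclass
class RunResult:
    """Everything a single run produces."""

    maps: spectral_maps.LTGMaps
    sai: sai_metrics.SAIResult
    gww: kymography.GWW
    roi: roi_geometry.FoldROI
    offsets: preprocess.FrameOffsets
    axis: GlottalAxis
    global_f0: float
    f0_gww: float | None
    max_opening_frame: int
    manifest: list = field(default_factory=list)
    timings: dict = field(default_factory=dict)


def load_landmarks(source) -> dict:
    """Load a landmark payload from a dict, JSON or YAML file."""
    if source is None:
        raise ConfigurationError("no landmark file given; axis and nodes are required")
    if isinstance(source, dict):
        lm = source
    else:
        p = Path(source)
        if not p.exists():
            raise ConfigurationError(f"landmark file not found: {p}")
        text = p.read_text()
        if p.suffix in (".yaml", ".yml"):
            import yaml

            lm = yaml.safe_load(text)
        else:
            lm = json.loads(text)
    if "axis" not in lm or "nodes" not in lm:
        raise ConfigurationError("landmarks must contain 'axis' and 'nodes'")
    axis = np.asarray(lm["axis"], dtype=float)
    if axis.shape != (2, 2):
        raise ConfigurationError("landmark 'axis' must be two (x, y) endpoints")
    nodes = np.asarray(lm["nodes"], dtype=float)
    if nodes.ndim != 2 or nodes.shape[1] != 2 or len(nodes) > 20:
        raise ConfigurationError("landmark 'nodes' must be up to 20 (x, y) points")
    return {
        "axis": axis,
        "nodes": nodes,
        "reference_frame": lm.get("reference_frame", "auto"),
    }


def _timed(timings: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, *exc):
            dt = time.perf_counter() - self.t0
            timings[name] = dt
            log.info("stage %-18s %.3f s", name, dt)
            return False

    return _Ctx()


def run_on_recording(
    rec: HSVRecording, landmarks, cfg: RunConfig | None = None
) -> RunResult:
    """Run the full analysis on an in-memory recording.

    ``landmarks`` is a landmark payload (dict or file); ``cfg`` supplies
    the remaining parameters (its ``input_path`` is ignored).
    """
    cfg = cfg or RunConfig()
    lm = load_landmarks(landmarks)
    timings: dict[str, float] = {}

    with _timed(timings, "channels"):
        red = preprocess.extract_channel(rec, "fold_contrast")
        glare = preprocess.glare_mask(rec)
    with _timed(timings, "offsets"):
        offsets = preprocess.estimate_offsets(red, cfg.search_radius)
        rec_stab = preprocess.stabilize(rec, offsets)
        red = preprocess.stabilize(red, offsets)
    with _timed(timings, "max_opening"):
        if lm["reference_frame"] == "auto":
            ref_idx = preprocess.select_max_opening_frame(
                red, dark_quantile=cfg.dark_quantile
            )
        else:
            ref_idx = int(lm["reference_frame"])
    with _timed(timings, "rotation"):
        axis = GlottalAxis(tuple(lm["axis"][0]), tuple(lm["axis"][1]))
        angle = axis.angle
        red, new_axis = preprocess.rotate_to_vertical(red, axis)
        h, w = red.shape
        nodes = (
            preprocess.rotate_points(lm["nodes"], -angle, (h, w))
            if abs(angle) > 1e-12
            else lm["nodes"]
        )
        if abs(angle) > 1e-12:
            # glare was estimated on the unrotated stack; rotate the mask
            glare = (
                preprocess.rotate_frames(
                    glare[None].astype(float), -angle
                )[0]
                > 0.5
            )
    with _timed(timings, "roi"):
        roi = roi_geometry.FoldROI.from_nodes(
            nodes, (h, w), axis_x=new_axis.x_mid
        )
    with _timed(timings, "global_f0"):
        global_f0 = spectral_maps.estimate_global_f0(
            red, roi, band=cfg.band, peak_floor=cfg.peak_floor, window=cfg.window
        )
    with _timed(timings, "maps"):
        maps = spectral_maps.build_ltg_maps(
            red,
            roi,
            global_f0,
            amp_threshold=cfg.amp_threshold,
            band=cfg.band,
            peak_floor=cfg.peak_floor,
            glare=glare,
            window=cfg.window,
        )
    with _timed(timings, "sai"):
        sai = sai_metrics.compute_sai(
            roi.left_mask, roi.right_mask, maps.vibrating_mask, cfg.affected_side
        )
    with _timed(timings, "gww"):
        gww = kymography.extract_gww(
            red, roi, row="mid-axis", dark_quantile=cfg.dark_quantile
        )
        f0_gww = kymography.f0_from_gww(gww, red.fps, band=cfg.band)

    manifest: list[str] = []
    if cfg.out_dir is not None:
        with _timed(timings, "export"):
            out_dir = Path(cfg.out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            manifest += video_io.write_maps(
                maps, out_dir, formats=set(cfg.export_formats)
            )
            gww_path = out_dir / "gww.csv"
            np.savetxt(
                gww_path,
                np.column_stack([np.arange(len(gww.widths)), gww.widths]),
                delimiter=",",
                header="frame,width_px",
                comments="",
                fmt="%.10g",
            )
            manifest.append(str(gww_path))
            results = {
                "subject_id": cfg.subject_id or rec.source_id,
                "global_f0_ltg_hz": global_f0,
                "f0_gww_hz": f0_gww,
                "max_opening_frame": ref_idx,
                "axis_angle_deg": angle,
                "AVF": sai.avf,
                "AVF_F0": sai.avf_f0,
                "NAVF": sai.navf,
                "NAVF_F0": sai.navf_f0,
                "SAI": sai.sai,
                "affected_side": sai.affected_side,
            }
            rpath = out_dir / "results.json"
            rpath.write_text(json.dumps(results, indent=1))
            manifest.append(str(rpath))

    return RunResult(
        maps=maps,
        sai=sai,
        gww=gww,
        roi=roi,
        offsets=offsets,
        axis=new_axis,
        global_f0=global_f0,
        f0_gww=f0_gww,
        max_opening_frame=ref_idx,
        manifest=manifest,
        timings=timings,
    )


def run_single(cfg: RunConfig) -> RunResult:
    """Read the configured recording and run the full analysis."""
    if cfg.input_path is None:
        raise ConfigurationError("input_path is required")
    lm = load_landmarks(cfg.landmarks)  # validate before the heavy read
    rec = video_io.read_recording(cfg.input_path, fps_override=cfg.fps)
    return run_on_recording(rec, lm, cfg)


def _boxplot(groups: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = list(groups)
    ax.boxplot([groups[g] for g in labels], tick_labels=labels)
    ax.set_ylabel("SAI")
    ax.set_title("Stiffness Asymmetry Index by group")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def run_cohort(
    runs: "list[tuple]",
    out_dir: str | Path | None = None,
):
    """Run a labeled cohort and compare groups.

    ``runs`` is a list of ``(recording_or_result, landmarks, label)`` or
    ``(RunConfig, label)`` tuples; recordings may be in-memory
    :class:`HSVRecording` objects or paths via RunConfig.  Returns
    ``(table, comparison)`` where ``table`` is a per-subject pandas
    DataFrame and ``comparison`` a :class:`~laryngotopo.sai_metrics.GroupComparison`
    (None with a warning when only one group is present).
    """
    import pandas as pd

    rows = []
    groups: dict[str, list[float]] = {}
    for item in runs:
        if len(item) == 2:
            cfg, label = item
            res = run_single(cfg)
            sid = cfg.subject_id or str(cfg.input_path)
        else:
            rec, lm, label = item
            res = run_on_recording(rec, lm)
            sid = rec.source_id
        rows.append(
            {
                "subject_id": sid,
                "group": label,
                "AVF": res.sai.avf,
                "AVF_F0": res.sai.avf_f0,
                "NAVF": res.sai.navf,
                "NAVF_F0": res.sai.navf_f0,
                "SAI": res.sai.sai,
                "global_F0_ltg": res.global_f0,
                "F0_gww": res.f0_gww,
            }
        )
        groups.setdefault(label, []).append(res.sai.sai)
    table = pd.DataFrame(rows)

    comparison = None
    if len(groups) < 2:
        import warnings

        warnings.warn("single group: summaries only, no pairwise tests")
    else:
        comparison = sai_metrics.compare_groups(groups)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "cohort_results.csv", index=False)
        if comparison is not None:
            payload = {
                "summaries": comparison.summaries,
                "p_values": {
                    f"{a} vs {b}": p for (a, b), p in comparison.p_values.items()
                },
            }
            (out_dir / "group_comparison.json").write_text(
                json.dumps(payload, indent=1)
            )
        _boxplot(groups, out_dir / "sai_boxplot.png")
    return table, comparison
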