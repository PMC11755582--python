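"""End-to-end orchestration: video in, PAR and report tables out.

``process_video`` is the library entry point used by the CLI, the batch
runner and the reproduction script: initial-frame selection, Viterbi
segmentation, optional correction, optical-flow propagation plus point
tracking, thickness traces, phase detection and the per-repetition PAR.
``run_pipeline`` wraps it with file I/O, stage accounting and a manifest
(config echo, per-stage status, output hashes) for provenance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .parstats import compute_par
from .segment import (
    ViterbiConfig,
    apply_correction,
    sobel_edge_energy,
    segment_fasciae,
    select_initial_frame,
)
from .thickness import (
    PhaseParams,
    build_traces,
    detect_contraction_phase,
    summarize_phases,
    summary_to_par_inputs,
)
from .track import TrackerConfig, place_measurement_points, track_video
from .video import UltrasoundVideo, read_video


@dataclass
class QualityReport:
    """Per-video quality score used for explicit (flag-only) gating."""

    sobel_energy: float
    frame_correlation: float
    flagged: bool
    reason: str = ""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every field is echoed in the manifest."""

    input: str | None  # TIFF path or PNG directory
    pixel_spacing: float = 0.1
    frame_rate: float | None = None
    output_dir: str = "fasciatrack_out"
    seed: int = 0
    viterbi: ViterbiConfig = field(default_factory=ViterbiConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    phase: PhaseParams = field(default_factory=PhaseParams)
    correction: str | None = None  # JSON correction file for the initial frame
    extra_keyframes: tuple[int, ...] = ()  # additionally segmented frames
    rest_mode: str = "pre"
    min_sobel_energy: float = 1.0  # permissive: low scores flag, never drop
    min_frame_correlation: float = 0.2


def validate_video(
    path: str | Path,
    pixel_spacing: float,
    frame_rate: float | None = None,
    min_sobel_energy: float = 1.0,
    min_frame_correlation: float = 0.2,
) -> tuple[UltrasoundVideo, QualityReport]:
    """Load a frame stack and score its quality.

    The quality score combines mean Sobel edge energy (are boundaries
    visible at all?) and mean adjacent-frame correlation (is the content
    coherent over time?). Below-threshold videos are flagged, not dropped —
    exclusion stays an explicit, logged decision.
    """
    video = read_video(path, pixel_spacing=pixel_spacing, frame_rate=frame_rate)
    energy = float(np.mean([sobel_edge_energy(f) for f in video.frames]))
    if video.n_frames > 1:
        corrs = []
        for a, b in zip(video.frames[:-1], video.frames[1:]):
            fa, fb = a.astype(float).ravel(), b.astype(float).ravel()
            if fa.std() == 0 or fb.std() == 0:
                corrs.append(0.0)
            else:
                corrs.append(float(np.corrcoef(fa, fb)[0, 1]))
        corr = float(np.mean(corrs))
    else:
        corr = 1.0
    reasons = []
    if energy < min_sobel_energy:
        reasons.append(f"sobel energy {energy:.2f} < {min_sobel_energy}")
    if corr < min_frame_correlation:
        reasons.append(f"frame correlation {corr:.2f} < {min_frame_correlation}")
    return video, QualityReport(
        sobel_energy=energy, frame_correlation=corr,
        flagged=bool(reasons), reason="; ".join(reasons),
    )


def process_video(
    video: UltrasoundVideo,
    viterbi: ViterbiConfig | None = None,
    tracker: TrackerConfig | None = None,
    phase: PhaseParams | None = None,
    correction: str | Path | dict | None = None,
    extra_keyframes: tuple[int, ...] = (),
    rest_mode: str = "pre",
) -> dict:
    """Run the full measurement chain on one loaded video.

    Returns a dict with the initial frame index, per-frame segmentations,
    tracks, trace, phase annotation, phase summary and the PAR.
    """
    viterbi = viterbi or ViterbiConfig()
    tracker = tracker or TrackerConfig()
    phase = phase or PhaseParams()

    initial = select_initial_frame(video)
    seg0 = segment_fasciae(video.frames[initial], viterbi, frame_index=initial)
    if correction is not None:
        seg0 = apply_correction(seg0, correction)
    keyframes = {initial: seg0}
    for k in extra_keyframes:
        if k != initial:
            keyframes[k] = segment_fasciae(video.frames[k], viterbi, frame_index=k)
    points = place_measurement_points(seg0)
    segs, tracks = track_video(video, keyframes, points=points, config=tracker)
    trace = build_traces(segs, tracks, video)
    phases = detect_contraction_phase(trace, muscle="TrA", params=phase)
    result = {
        "initial_frame": initial,
        "segmentations": segs,
        "tracks": tracks,
        "trace": trace,
        "phases": phases,
        "summary": None,
        "par": None,
        "par_inputs": None,
    }
    if phases.detected:
        summary = summarize_phases(trace, phases, rest_mode=rest_mode)
        inputs = summary_to_par_inputs(summary)
        result["summary"] = summary
        result["par_inputs"] = inputs
        result["par"] = compute_par(
            inputs["TrA_R"], inputs["OI_R"], inputs["OE_R"],
            inputs["TrA_C"], inputs["OI_C"], inputs["OE_C"],
        )
    else:
        warnings.warn("no contracted phase detected; PAR not computed")
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: RunConfig) -> dict:
    echo = asdict(config)
    return echo


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline on disk: stage-by-stage, with a provenance manifest.

    On stage failure the manifest records the failure point and downstream
    stages are skipped; the manifest is always written. Returns the
    manifest dict (also at ``<output_dir>/manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": _config_echo(config),
        "stages": {},
        "outputs": {},
        "counters": {"processed": 0, "flagged": 0, "failed": 0},
    }

    def finish() -> dict:
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    def record_output(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    # stage: validate ----------------------------------------------------
    try:
        if config.input is None:
            raise ValueError("RunConfig.input is required for run_pipeline")
        video, quality = validate_video(
            config.input, config.pixel_spacing, config.frame_rate,
            config.min_sobel_energy, config.min_frame_correlation,
        )
        manifest["stages"]["validate"] = {
            "status": "ok", "n_frames": video.n_frames,
            "quality": asdict(quality),
        }
        if quality.flagged:
            manifest["counters"]["flagged"] += 1
    except Exception as exc:  # noqa: BLE001 - manifest records any failure
        manifest["stages"]["validate"] = {"status": "failed", "error": str(exc)}
        manifest["counters"]["failed"] += 1
        return finish()

    # stage: measure (segmentation -> tracking -> trace -> phases -> PAR)
    try:
        result = process_video(
            video,
            viterbi=config.viterbi,
            tracker=config.tracker,
            phase=config.phase,
            correction=config.correction,
            extra_keyframes=config.extra_keyframes,
            rest_mode=config.rest_mode,
        )
        manifest["stages"]["segment"] = {
            "status": "ok", "initial_frame": result["initial_frame"],
        }
        seg_path = out / "initial_segmentation.json"
        result["segmentations"][result["initial_frame"]].to_json(seg_path)
        record_output("initial_segmentation", seg_path)

        tracks_path = out / "tracks.csv"
        result["tracks"].to_csv(tracks_path, index=False, float_format="%.6f")
        record_output("tracks", tracks_path)
        manifest["stages"]["track"] = {
            "status": "ok",
            "n_lost": int((result["tracks"]["flag"] == "lost").sum()),
        }

        trace_path = out / "trace.csv"
        result["trace"].to_csv(trace_path, index=False, float_format="%.6f")
        record_output("trace", trace_path)
        manifest["stages"]["measure"] = {"status": "ok"}

        phases = result["phases"]
        phases_path = out / "phases.json"
        phases_path.write_text(json.dumps(
            {"rest": [list(i) for i in phases.rest],
             "contracted": [list(i) for i in phases.contracted],
             "params": asdict(phases.params)}
        ))
        record_output("phases", phases_path)
        manifest["stages"]["phases"] = {
            "status": "ok", "detected": phases.detected,
        }

        if result["par"] is not None:
            par_path = out / "par.csv"
            row = {**result["par_inputs"], "PAR": result["par"]}
            pd.DataFrame([row]).to_csv(par_path, index=False, float_format="%.6f")
            record_output("par", par_path)
            manifest["stages"]["par"] = {"status": "ok", "PAR": result["par"]}
        else:
            manifest["stages"]["par"] = {
                "status": "skipped", "reason": "no contracted phase detected",
            }
        manifest["counters"]["processed"] += 1
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["measure"] = {"status": "failed", "error": str(exc)}
        manifest["counters"]["failed"] += 1
    return finish()
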