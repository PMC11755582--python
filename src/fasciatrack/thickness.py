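"""Calibrated thickness traces, contraction-phase detection and phase means.

A muscle's thickness at a measurement point is the vertical distance (same
column) from the tracked point on its upper fascia down to its lower
boundary, converted to mm with the pixel calibration. Collecting this over
all frames, muscles and points gives the tidy thickness trace from which
the contraction phase is detected and the rest/contracted summary
thicknesses (the inputs of the preferential activation ratio) are taken.

Phase detection runs on the 3-point mean TrA thickness: after a short
moving-median smoothing, the baseline is the median of an initial rest
window; the contracted phase is the longest run above
``baseline + enter_fraction * (peak - baseline)``, extended by hysteresis
down to ``baseline + exit_fraction * (peak - baseline)``. A trace with no
rise above baseline yields an empty contracted interval and a warning, not
an error. The rule is invariant to adding a constant to the whole trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .segment import FasciaSegmentation
from .video import UltrasoundVideo

MUSCLES = ("OE", "OI", "TrA")


@dataclass
class PhaseParams:
    """Contraction-detection parameters (fractions are of peak - baseline)."""

    baseline_fraction: float = 0.15  # leading fraction of frames used as baseline
    smooth_window: int = 5  # moving-median width, frames
    enter_fraction: float = 0.5
    exit_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.baseline_fraction < 1:
            raise ValueError("baseline_fraction must be in (0, 1)")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not 0 < self.exit_fraction <= self.enter_fraction < 1:
            raise ValueError("need 0 < exit_fraction <= enter_fraction < 1")


@dataclass
class PhaseAnnotation:
    """Rest and contracted frame intervals, 0-based half-open."""

    rest: list[tuple[int, int]]
    contracted: list[tuple[int, int]]
    params: PhaseParams = field(default_factory=PhaseParams)

    @property
    def detected(self) -> bool:
        return any(b > a for a, b in self.contracted)


def thickness_at_point(
    segmentation: FasciaSegmentation,
    muscle: str,
    point: tuple[float, float],
    pixel_spacing: float,
) -> float:
    """Thickness (mm) at one tracked point: vertical gap to the lower boundary."""
    if muscle not in MUSCLES:
        raise ValueError(f"unknown muscle {muscle!r}")
    if not pixel_spacing > 0:
        raise ValueError(f"pixel_spacing must be > 0, got {pixel_spacing}")
    row, col = point
    c0, c1 = segmentation.column_range
    if not c0 <= col <= c1 - 1:
        raise ValueError(f"point column {col} outside column range [{c0}, {c1})")
    mi = MUSCLES.index(muscle)
    grid = np.arange(c0, c1, dtype=float)
    lower = float(np.interp(col, grid, segmentation.boundaries[mi + 1]))
    if lower <= row:
        raise ValueError(
            f"lower boundary (row {lower:.1f}) not below point (row {row:.1f}) "
            f"for muscle {muscle} at column {col:.1f}"
        )
    return (lower - row) * pixel_spacing


def build_traces(
    segmentations: dict[int, FasciaSegmentation],
    tracks: pd.DataFrame,
    video: UltrasoundVideo,
) -> pd.DataFrame:
    """Per-(frame, muscle, point) thickness table.

    Flagged (lost) points are carried as missing thickness, never dropped.
    Raises when any muscle lacks a valid point on more than half of the
    frames — below that coverage the trace is not usable for phase means.
    """
    n_frames = video.n_frames
    frame_rate = video.frame_rate or 1.0
    rows = []
    for rec in tracks.itertuples(index=False):
        seg = segmentations.get(rec.frame)
        if seg is None:
            raise ValueError(f"no segmentation for frame {rec.frame}")
        flagged = bool(rec.flag)
        value = np.nan
        if not flagged:
            try:
                value = thickness_at_point(
                    seg, rec.muscle, (rec.row, rec.col), video.pixel_spacing
                )
            except ValueError:
                flagged = True
        rows.append(
            {"frame": rec.frame, "time_s": rec.frame / frame_rate,
             "muscle": rec.muscle, "point_id": rec.point_id,
             "thickness_mm": value, "flag": "lost" if flagged else ""}
        )
    trace = pd.DataFrame(rows)
    for m in MUSCLES:
        sub = trace[trace["muscle"] == m]
        valid_frames = sub.dropna(subset=["thickness_mm"])["frame"].nunique()
        if valid_frames < 0.5 * n_frames:
            raise ValueError(
                f"muscle {m}: valid thickness on only {valid_frames}/{n_frames} frames"
            )
    return trace


def _muscle_mean_series(trace: pd.DataFrame, muscle: str) -> np.ndarray:
    sub = trace[trace["muscle"] == muscle]
    series = sub.groupby("frame")["thickness_mm"].mean()
    n_frames = int(trace["frame"].max()) + 1
    out = np.full(n_frames, np.nan)
    out[series.index.to_numpy()] = series.to_numpy()
    # interior gaps from flagged frames are linearly interpolated
    return pd.Series(out).interpolate(limit_direction="both").to_numpy()


def detect_contraction_phase(
    trace: pd.DataFrame,
    muscle: str = "TrA",
    params: PhaseParams | None = None,
) -> PhaseAnnotation:
    """Detect the contracted interval on a muscle's 3-point mean thickness."""
    params = params or PhaseParams()
    series = _muscle_mean_series(trace, muscle)
    n = len(series)
    if n < 20:
        raise ValueError(f"need >= 20 frames for phase detection, got {n}")
    smoothed = median_filter(series, size=params.smooth_window, mode="nearest")
    n_base = max(1, int(round(params.baseline_fraction * n)))
    baseline = float(np.median(smoothed[:n_base]))
    peak = float(smoothed.max())
    if peak <= baseline:
        warnings.warn("no contraction detected: peak does not exceed baseline")
        return PhaseAnnotation(rest=[(0, n)], contracted=[], params=params)
    thr_in = baseline + params.enter_fraction * (peak - baseline)
    thr_out = baseline + params.exit_fraction * (peak - baseline)
    above = smoothed >= thr_in
    if not above.any():
        warnings.warn("no contraction detected: no frames above entry threshold")
        return PhaseAnnotation(rest=[(0, n)], contracted=[], params=params)
    # longest run above the entry threshold
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(n)
    runs = sorted(zip(starts, ends), key=lambda se: (-(se[1] - se[0]), se[0]))
    s, e = int(runs[0][0]), int(runs[0][1])
    # hysteresis: extend both ways while above the exit threshold
    while s > 0 and smoothed[s - 1] >= thr_out:
        s -= 1
    while e < n and smoothed[e] >= thr_out:
        e += 1
    rest = []
    if s > 0:
        rest.append((0, s))
    if e < n:
        rest.append((e, n))
    return PhaseAnnotation(rest=rest, contracted=[(s, e)], params=params)


def summarize_phases(
    trace: pd.DataFrame,
    phases: PhaseAnnotation,
    rest_mode: str = "pre",
) -> pd.DataFrame:
    """Per-muscle rest and contracted mean thickness (mm).

    The 3-point mean is taken per frame first, then averaged over the
    phase's frames. ``rest_mode`` selects which rest frames enter the rest
    mean: ``pre`` (default, the interval before contraction onset) or
    ``pooled`` (all rest intervals). Muscles with missing points use the
    available points; the number of contributing frames is reported.
    """
    if rest_mode not in ("pre", "pooled"):
        raise ValueError(f"rest_mode must be 'pre' or 'pooled', got {rest_mode!r}")
    if not phases.detected:
        raise ValueError("cannot summarize: empty contracted interval")
    if not phases.rest:
        raise ValueError("cannot summarize: no rest frames")
    rest_intervals = phases.rest if rest_mode == "pooled" else phases.rest[:1]

    def frame_set(intervals):
        idx = np.concatenate([np.arange(a, b) for a, b in intervals])
        return idx

    rest_idx = frame_set(rest_intervals)
    con_idx = frame_set(phases.contracted)
    rows = []
    for m in MUSCLES:
        series = _muscle_mean_series(trace, m)
        rows.append(
            {"muscle": m,
             "rest_mm": float(np.nanmean(series[rest_idx])),
             "contracted_mm": float(np.nanmean(series[con_idx])),
             "n_rest_frames": int(len(rest_idx)),
             "n_contracted_frames": int(len(con_idx))}
        )
    return pd.DataFrame(rows)


def summary_to_par_inputs(summary: pd.DataFrame) -> dict[str, float]:
    """Six PAR inputs (``TrA_R`` ... ``OE_C``) from a phase summary table."""
    s = summary.set_index("muscle")
    return {
        "TrA_R": s.loc["TrA", "rest_mm"], "OI_R": s.loc["OI", "rest_mm"],
        "OE_R": s.loc["OE", "rest_mm"], "TrA_C": s.loc["TrA", "contracted_mm"],
        "OI_C": s.loc["OI", "contracted_mm"], "OE_C": s.loc["OE", "contracted_mm"],
    }


def plot_trace(trace: pd.DataFrame, phases: PhaseAnnotation | None = None, ax=None):
    """Thickness traces per muscle with the contracted interval shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    for m in MUSCLES:
        series = _muscle_mean_series(trace, m)
        ax.plot(np.arange(len(series)), series, label=m)
    if phases is not None:
        for a, b in phases.contracted:
            ax.axvspan(a, b, alpha=0.2, color="red")
    ax.set_xlabel("frame")
    ax.set_ylabel("thickness [mm]")
    ax.legend(loc="upper right")
    return ax
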