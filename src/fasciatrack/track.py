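"""Optical-flow propagation of the segmentation and measurement-point tracking.

The initial (keyframe) segmentation is carried to every other frame with a
dense iterative Lucas-Kanade flow field; three measurement points per
muscle, placed on each muscle's upper fascia in the keyframe, are tracked
by sampling the same kind of flow field at the point locations. For every
frame the reference is not necessarily its direct predecessor: it is the
already-segmented frame with the highest zero-normalized cross-correlation
to the current frame, which makes the tracking robust to transient image
degradation.

Parameter semantics (the defaults follow the tracking configuration the
pipeline was designed around):

- ``sigma`` (0.04): Gaussian pre-smoothing of the frames before flow
  estimation, expressed as a fraction of the Lucas-Kanade window; the
  pixel sigma is ``sigma * window``.
- ``fgs_lambda`` (5000) / ``fgs_sigma`` (3): an edge-aware post-filter on
  the flow field — a normalized (weighted) Gaussian smoothing whose
  spatial scale grows with ``fgs_lambda`` and whose weights decay with the
  reference image's gradient magnitude at rate ``1/fgs_sigma``, so the
  field is smoothed within tissue regions but not blindly across fasciae.
- ``window`` (21 px) and ``levels`` (3): Lucas-Kanade window size and the
  number of coarse-to-fine warping iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import optical_flow_ilk
from skimage.transform import resize

from .segment import FasciaSegmentation, enforce_ordering
from .video import UltrasoundVideo

MUSCLES = ("OE", "OI", "TrA")
#: fraction of the column range at which the three points sit
POINT_FRACTIONS = (0.4, 0.5, 0.6)


@dataclass
class TrackerConfig:
    """Tracking parameters; see the module docstring for semantics."""

    sigma: float = 0.04
    fgs_lambda: float = 5000.0
    fgs_sigma: float = 3.0
    window: int = 21
    levels: int = 3
    downscale: int = 2  # flow computed at 1/downscale resolution

    def __post_init__(self) -> None:
        for name in ("sigma", "fgs_lambda", "fgs_sigma", "window", "levels", "downscale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class MeasurementPoints:
    """Three (row, col) points per muscle, placed on a given frame."""

    frame_index: int
    points: dict[str, np.ndarray]  # muscle -> (3, 2) array of (row, col)

    def __post_init__(self) -> None:
        for m in MUSCLES:
            if m not in self.points:
                raise ValueError(f"missing points for muscle {m!r}")
            arr = np.asarray(self.points[m], dtype=float)
            if arr.shape != (3, 2):
                raise ValueError(f"points for {m!r} must have shape (3, 2), got {arr.shape}")
            self.points[m] = arr

    def as_array(self) -> np.ndarray:
        """(9, 2) array in (OE, OI, TrA) x (point 0, 1, 2) order."""
        return np.concatenate([self.points[m] for m in MUSCLES])


def place_measurement_points(segmentation: FasciaSegmentation) -> MeasurementPoints:
    """Place 3 points per muscle on its upper fascia.

    Points sit at 40%, 50% and 60% of the segmentation's column range (the
    middle of the fascia), with rows interpolated from the polyline.
    """
    c0, c1 = segmentation.column_range
    span = c1 - c0
    if span < 5:
        raise ValueError(f"column range {segmentation.column_range} too narrow (< 5 px)")
    cols = np.asarray([c0 + f * (span - 1) for f in POINT_FRACTIONS])
    grid = np.arange(c0, c1, dtype=float)
    points = {}
    for mi, m in enumerate(MUSCLES):
        rows = np.interp(cols, grid, segmentation.boundaries[mi])
        points[m] = np.column_stack([rows, cols])
    return MeasurementPoints(frame_index=segmentation.frame_index, points=points)


def select_reference_frame(
    current: np.ndarray,
    candidates: dict[int, np.ndarray],
    region: tuple[slice, slice] | None = None,
) -> int:
    """Candidate frame index with the highest correlation to ``current``.

    Correlation is the zero-normalized (Pearson) cross-correlation over
    ``region`` (whole frame when None). Ties break toward the lowest index;
    zero-variance frames make the correlation undefined and raise.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    reg = region if region is not None else (slice(None), slice(None))
    cur = np.asarray(current, dtype=float)[reg].ravel()
    if cur.std() == 0:
        raise ValueError("current frame has zero variance in the comparison region")
    best_idx, best_corr = None, -np.inf
    for idx in sorted(candidates):
        cand = np.asarray(candidates[idx], dtype=float)[reg].ravel()
        if cand.std() == 0:
            raise ValueError(f"candidate frame {idx} has zero variance in the comparison region")
        corr = float(np.corrcoef(cur, cand)[0, 1])
        if corr > best_corr:
            best_idx, best_corr = idx, corr
    return best_idx


def dense_flow(
    reference: np.ndarray, target: np.ndarray, config: TrackerConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dense displacement field from ``reference`` to ``target``.

    Returns ``(v, u)`` such that a feature at (r, c) in the reference lies
    at (r + v[r, c], c + u[r, c]) in the target. Computed by iterative
    Lucas-Kanade at reduced resolution, rescaled, then post-smoothed by the
    edge-aware filter described in the module docstring.
    """
    config = config or TrackerConfig()
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape or ref.ndim != 2:
        raise ValueError("reference and target must be 2-D frames of equal shape")
    pre = config.sigma * config.window
    if pre > 0:
        ref_s = ndimage.gaussian_filter(ref, pre)
        tgt_s = ndimage.gaussian_filter(tgt, pre)
    else:
        ref_s, tgt_s = ref, tgt
    d = config.downscale
    if d > 1:
        small = (max(8, ref.shape[0] // d), max(8, ref.shape[1] // d))
        ref_w = resize(ref_s, small, anti_aliasing=True)
        tgt_w = resize(tgt_s, small, anti_aliasing=True)
    else:
        ref_w, tgt_w = ref_s, tgt_s
    radius = max(3, config.window // (2 * d))
    v, u = optical_flow_ilk(
        ref_w, tgt_w, radius=radius, num_warp=config.levels, gaussian=False,
        prefilter=True,
    )
    if d > 1:
        scale_r = ref.shape[0] / ref_w.shape[0]
        scale_c = ref.shape[1] / ref_w.shape[1]
        v = resize(v, ref.shape) * scale_r
        u = resize(u, ref.shape) * scale_c
    return _edge_aware_smooth(v, ref, config), _edge_aware_smooth(u, ref, config)


def _edge_aware_smooth(
    flow: np.ndarray, guide: np.ndarray, config: TrackerConfig
) -> np.ndarray:
    """Normalized-convolution smoothing weighted against guide-image edges."""
    gy = ndimage.sobel(guide, axis=0, mode="reflect")
    gx = ndimage.sobel(guide, axis=1, mode="reflect")
    grad = np.hypot(gx, gy) / 8.0  # per-pixel gradient on the intensity scale
    w = np.exp(-grad / config.fgs_sigma)
    sigma = np.sqrt(config.fgs_lambda) / 25.0
    num = ndimage.gaussian_filter(flow * w, sigma)
    den = ndimage.gaussian_filter(w, sigma)
    return num / np.maximum(den, 1e-8)


def _sample_flow(
    v: np.ndarray, u: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """Bilinear flow samples at (row, col) positions; returns (n, 2) displacements."""
    coords = positions.T  # (2, n): rows, cols
    dv = ndimage.map_coordinates(v, coords, order=1, mode="nearest")
    du = ndimage.map_coordinates(u, coords, order=1, mode="nearest")
    return np.column_stack([dv, du])


def _segmentation_region(
    segs: dict[int, FasciaSegmentation], shape: tuple[int, int], pad: int = 15
) -> tuple[slice, slice]:
    """Row band spanned by the keyframe boundaries, padded; full column range."""
    lo = min(int(np.floor(s.boundaries.min())) for s in segs.values()) - pad
    hi = max(int(np.ceil(s.boundaries.max())) for s in segs.values()) + pad
    return slice(max(0, lo), min(shape[0], hi)), slice(None)


def _processing_order(n_frames: int, keyframes: set[int]) -> list[int]:
    """Non-keyframe indices ordered by distance to the nearest keyframe."""
    others = [t for t in range(n_frames) if t not in keyframes]
    return sorted(others, key=lambda t: (min(abs(t - k) for k in keyframes), t))


def _apply_flow_to_boundaries(
    seg: FasciaSegmentation, v: np.ndarray, u: np.ndarray, frame_index: int,
    shape: tuple[int, int],
) -> FasciaSegmentation:
    """Displace a segmentation by a dense flow field and re-grid per column."""
    c0, c1 = seg.column_range
    cols = np.arange(c0, c1, dtype=float)
    new_bounds = np.empty_like(seg.boundaries)
    for bi in range(seg.boundaries.shape[0]):
        pos = np.column_stack([seg.boundaries[bi], cols])
        disp = _sample_flow(v, u, pos)
        moved_r = seg.boundaries[bi] + disp[:, 0]
        moved_c = cols + disp[:, 1]
        order = np.argsort(moved_c, kind="stable")
        new_bounds[bi] = np.interp(cols, moved_c[order], moved_r[order])
    new_bounds = np.clip(enforce_ordering(new_bounds), 0, shape[0] - 1)
    return FasciaSegmentation(
        frame_index=frame_index, boundaries=new_bounds,
        column_range=seg.column_range, source="propagated",
    )


def track_video(
    video: UltrasoundVideo,
    keyframe_segmentations: dict[int, FasciaSegmentation],
    points: MeasurementPoints | None = None,
    config: TrackerConfig | None = None,
) -> tuple[dict[int, FasciaSegmentation], pd.DataFrame | None]:
    """Propagate segmentations and (optionally) track points in one flow pass.

    Frames are processed outward from the keyframes; each frame's reference
    is the best-correlated already-segmented frame. Returns a per-frame
    segmentation dict and, if ``points`` is given, a tidy tracks table with
    columns (frame, muscle, point_id, row, col, flag). Points that drift
    out of the image are flagged ``lost`` (position frozen), never dropped.
    """
    config = config or TrackerConfig()
    if not keyframe_segmentations:
        raise ValueError("need at least one keyframe segmentation")
    n_frames = video.n_frames
    shape = video.shape
    for k in keyframe_segmentations:
        if not 0 <= k < n_frames:
            raise ValueError(f"keyframe index {k} outside video of {n_frames} frames")
    segs: dict[int, FasciaSegmentation] = dict(keyframe_segmentations)
    region = _segmentation_region(keyframe_segmentations, shape)

    track_pos: dict[int, np.ndarray] = {}
    track_flag: dict[int, np.ndarray] = {}
    if points is not None:
        if points.frame_index not in keyframe_segmentations:
            raise ValueError("measurement points must be placed on a keyframe")
        arr = points.as_array()
        if (arr[:, 0] < 0).any() or (arr[:, 1] < 0).any() or \
           (arr[:, 0] > shape[0] - 1).any() or (arr[:, 1] > shape[1] - 1).any():
            raise ValueError("measurement points must lie inside the image")
        track_pos[points.frame_index] = arr
        track_flag[points.frame_index] = np.zeros(len(arr), dtype=bool)

    order = _processing_order(n_frames, set(keyframe_segmentations))
    for t in order:
        candidates = {i: video.frames[i] for i in segs}
        try:
            ref = select_reference_frame(video.frames[t], candidates, region=region)
            v, u = dense_flow(video.frames[ref], video.frames[t], config)
        except ValueError as exc:
            raise ValueError(f"flow failed at frame {t}: {exc}") from exc
        segs[t] = _apply_flow_to_boundaries(segs[ref], v, u, t, shape)
        if points is not None:
            # points follow the same reference chain as the segmentation;
            # for references without tracked points (keyframes other than
            # the placement frame) fall back to the placement frame
            src = ref if ref in track_pos else points.frame_index
            if src != ref:
                v, u = dense_flow(video.frames[src], video.frames[t], config)
            pos = track_pos[src]
            disp = _sample_flow(v, u, pos)
            new = pos + disp
            lost = (
                (new[:, 0] < 0) | (new[:, 0] > shape[0] - 1)
                | (new[:, 1] < 0) | (new[:, 1] > shape[1] - 1)
            )
            flags = track_flag[src] | lost
            new[lost] = pos[lost]
            track_pos[t] = new
            track_flag[t] = flags

    tracks = None
    if points is not None:
        rows = []
        for t in range(n_frames):
            pos, flags = track_pos[t], track_flag[t]
            for i in range(9):
                rows.append(
                    {"frame": t, "muscle": MUSCLES[i // 3], "point_id": i % 3,
                     "row": pos[i, 0], "col": pos[i, 1],
                     "flag": "lost" if flags[i] else ""}
                )
        tracks = pd.DataFrame(rows)
        n_lost = int(tracks[tracks["frame"] == n_frames - 1]["flag"].eq("lost").sum())
        if n_lost == 9:
            raise ValueError("all measurement points were lost during tracking")
    return segs, tracks


def propagate_segmentation(
    video: UltrasoundVideo,
    keyframe_segmentations: dict[int, FasciaSegmentation],
    config: TrackerConfig | None = None,
) -> dict[int, FasciaSegmentation]:
    """Per-frame segmentations propagated from the keyframes (see track_video)."""
    segs, _ = track_video(video, keyframe_segmentations, points=None, config=config)
    return segs


def track_points(
    video: UltrasoundVideo,
    keyframe_segmentations: dict[int, FasciaSegmentation],
    points: MeasurementPoints,
    config: TrackerConfig | None = None,
) -> pd.DataFrame:
    """Per-frame tracked measurement points (see track_video)."""
    _, tracks = track_video(video, keyframe_segmentations, points=points, config=config)
    return tracks
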