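"""Initial-frame selection and Viterbi brightest-path fascia segmentation.

Fasciae appear as bright, roughly horizontal ridges in B-mode images of
the abdominal wall. Segmentation proceeds in three steps:

1. pick the initial frame whose Sobel edge energy is highest (the frame
   where muscle boundaries are most visible),
2. extract the four fascia boundaries as brightest left-to-right paths by
   dynamic programming (a Viterbi pass over columns), peeling paths off
   one by one with an exclusion band around each accepted path,
3. optionally merge operator-supplied corrections.

The path model maximizes summed brightness minus a per-pixel vertical-step
penalty, with the vertical step per column bounded. Ties are broken toward
the smallest row so results are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .video import UltrasoundVideo

N_BOUNDARIES = 4
#: boundary index -> meaning, top to bottom
BOUNDARY_NAMES = (
    "superficial_OE",
    "OE_OI_interface",
    "OI_TrA_interface",
    "deep_TrA",
)


@dataclass
class ViterbiConfig:
    """Parameters of the brightest-path dynamic program.

    ``max_vertical_step`` bounds |Delta row| per column transition;
    ``step_penalty`` is subtracted per pixel of vertical step (brightness
    units); ``exclusion_halfwidth`` masks rows around an accepted path
    before the next extraction; ``presmooth_sigma`` is a Gaussian blur
    applied before the DP to suppress isolated speckle maxima.
    """

    max_vertical_step: int = 2
    step_penalty: float = 2.0
    exclusion_halfwidth: int = 6
    presmooth_sigma: float = 1.0
    subpixel: bool = True  # parabolic ridge refinement after the DP pass

    def __post_init__(self) -> None:
        if self.max_vertical_step < 1:
            raise ValueError(f"max_vertical_step must be >= 1, got {self.max_vertical_step}")
        if self.step_penalty < 0 or self.exclusion_halfwidth < 0 or self.presmooth_sigma < 0:
            raise ValueError("penalties and widths must be >= 0")


@dataclass
class FasciaSegmentation:
    """Four ordered fascia polylines for one frame.

    ``boundaries`` has shape (4, n_cols): row coordinate per column, top to
    bottom (superficial OE border, OE/OI, OI/TrA, deep TrA border).
    ``column_range`` is 0-based half-open. ``source`` records provenance:
    ``automatic``, ``corrected`` or ``propagated``.
    """

    frame_index: int
    boundaries: np.ndarray
    column_range: tuple[int, int]
    source: str = "automatic"

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.boundaries.shape[0] != N_BOUNDARIES:
            raise ValueError(f"expected {N_BOUNDARIES} boundaries, got {self.boundaries.shape[0]}")
        if self.boundaries.shape[1] != self.column_range[1] - self.column_range[0]:
            raise ValueError("boundary length does not match column_range")
        self.validate()

    def validate(self) -> None:
        """Enforce strict top-to-bottom ordering in every column."""
        diffs = np.diff(self.boundaries, axis=0)
        bad = np.where((diffs <= 0).any(axis=0))[0]
        if bad.size:
            cols = (bad + self.column_range[0]).tolist()
            raise ValueError(f"boundaries cross or touch at columns {cols[:10]}"
                             + ("..." if len(cols) > 10 else ""))
        if (self.boundaries < 0).any():
            raise ValueError("boundary rows must be >= 0")

    @property
    def n_cols(self) -> int:
        return self.boundaries.shape[1]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "frame_index": self.frame_index,
            "column_range": list(self.column_range),
            "boundaries": self.boundaries.tolist(),
            "source": self.source,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "FasciaSegmentation":
        data = json.loads(Path(path).read_text())
        return cls(
            frame_index=data["frame_index"],
            boundaries=np.asarray(data["boundaries"], dtype=float),
            column_range=tuple(data["column_range"]),
            source=data.get("source", "automatic"),
        )


def sobel_edge_energy(frame: np.ndarray) -> float:
    """Mean Sobel gradient magnitude of a 2-D frame.

    Uses the standard 3x3 Sobel pair (reflect boundary handling); zero for
    a constant frame and linear in the contrast of a step edge.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D, got ndim={frame.ndim}")
    if min(frame.shape) < 3:
        raise ValueError(f"frame must be at least 3x3, got {frame.shape}")
    gy = ndimage.sobel(frame, axis=0, mode="reflect")
    gx = ndimage.sobel(frame, axis=1, mode="reflect")
    return float(np.hypot(gx, gy).mean())


def select_initial_frame(video: UltrasoundVideo) -> int:
    """Index of the frame with the highest Sobel edge energy (ties: lowest index)."""
    energies = [sobel_edge_energy(f) for f in video.frames]
    return int(np.argmax(energies))


def brightest_path(
    image: np.ndarray,
    row_band: tuple[int, int] | None = None,
    config: ViterbiConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Maximum-score left-to-right path through an image by dynamic programming.

    The path visits one row per column; the score is the summed brightness
    along the path minus ``step_penalty`` per pixel of vertical movement,
    with |Delta row| <= ``max_vertical_step`` between adjacent columns.
    Masked pixels may be ``-inf``. Ties are broken toward the smallest row
    (at the final column and at every predecessor choice).

    Returns ``(rows, score)`` where ``rows`` are integer row coordinates in
    the full-image frame, one per column.
    """
    config = config or ViterbiConfig()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    r0, r1 = row_band if row_band is not None else (0, image.shape[0])
    if not (0 <= r0 < r1 <= image.shape[0]):
        raise ValueError(f"empty or out-of-bounds row_band {row_band}")
    band = image[r0:r1]
    n_rows, n_cols = band.shape
    k = config.max_vertical_step
    penalty = config.step_penalty

    score = band[:, 0].copy()
    back = np.zeros((n_rows, n_cols), dtype=np.int32)
    for c in range(1, n_cols):
        best = np.full(n_rows, -np.inf)
        arg = np.zeros(n_rows, dtype=np.int32)
        # predecessor row = r + off; ascending off keeps the smallest
        # predecessor on ties (strict improvement required)
        for off in range(-k, k + 1):
            cand = np.full(n_rows, -np.inf)
            if off < 0:
                cand[-off:] = score[: n_rows + off]
            elif off > 0:
                cand[: n_rows - off] = score[off:]
            else:
                cand[:] = score
            cand = cand - penalty * abs(off)
            better = cand > best
            best[better] = cand[better]
            arg[better] = np.arange(n_rows, dtype=np.int32)[better] + off
        score = best + band[:, c]
        back[:, c] = arg
    if not np.isfinite(score).any():
        raise ValueError("no admissible path (all candidates masked)")
    end = int(np.argmax(score))  # first max = smallest row
    total = float(score[end])
    rows = np.empty(n_cols, dtype=int)
    rows[-1] = end
    for c in range(n_cols - 1, 0, -1):
        rows[c - 1] = back[rows[c], c]
    return rows + r0, total


def segment_fasciae(
    frame: np.ndarray, config: ViterbiConfig | None = None, frame_index: int = 0
) -> FasciaSegmentation:
    """Extract the four fascia boundaries of one frame.

    Paths are extracted sequentially in descending score order; after each
    accepted path an exclusion band of ``exclusion_halfwidth`` rows around
    it is masked so the next path cannot re-use the same ridge. Accepted
    paths are then ordered top to bottom and projected onto a strictly
    ordered set (minimum 1 px separation).
    """
    config = config or ViterbiConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    n_rows, n_cols = frame.shape
    needed = N_BOUNDARIES * (2 * config.exclusion_halfwidth + 1)
    if n_rows < max(needed, N_BOUNDARIES):
        raise ValueError(
            f"image with {n_rows} rows too short to place {N_BOUNDARIES} "
            f"non-crossing paths with exclusion halfwidth {config.exclusion_halfwidth}"
        )
    work = ndimage.gaussian_filter(frame, config.presmooth_sigma) if config.presmooth_sigma > 0 else frame.copy()
    masked = work.copy()
    paths = []
    row_idx = np.arange(n_rows)[:, None]
    if config.subpixel:
        # heavier smoothing along the fascia direction for localization only:
        # speckle averages out along the ridge without blurring its profile
        ridge = ndimage.gaussian_filter1d(work, sigma=4.0, axis=1)
    for _ in range(N_BOUNDARIES):
        rows, _score = brightest_path(masked, config=config)
        refined = _refine_subpixel(ridge, rows) if config.subpixel else rows.astype(float)
        paths.append(refined)
        band = np.abs(row_idx - rows[None, :]) <= config.exclusion_halfwidth
        masked[band] = -np.inf
    order = np.argsort([p.mean() for p in paths], kind="stable")
    boundaries = np.stack([paths[i] for i in order]).astype(float)
    boundaries = enforce_ordering(boundaries)
    return FasciaSegmentation(
        frame_index=frame_index,
        boundaries=boundaries,
        column_range=(0, n_cols),
        source="automatic",
    )


def _refine_subpixel(image: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Sub-pixel refinement of a ridge path.

    Re-centers each column on the local brightness maximum within +-2 rows
    of the DP path, then fits a parabola through the three rows around it
    and shifts to the apex (clamped to +-0.5 px). Columns at the image
    border or on a non-concave profile keep the re-centered integer row.
    """
    n_rows = image.shape[0]
    cols = np.arange(image.shape[1])
    window = np.arange(-2, 3)
    neighborhood = image[
        np.clip(rows[None, :] + window[:, None], 0, n_rows - 1), cols[None, :]
    ]
    centered = rows + window[np.argmax(neighborhood, axis=0)]
    centered = np.clip(centered, 0, n_rows - 1)
    refined = centered.astype(float)
    interior = (centered > 0) & (centered < n_rows - 1)

    def at(offset):
        return image[np.clip(centered + offset, 0, n_rows - 1), cols]

    # remove the locally linear tissue background (sampled 4 px off-crest on
    # either side) so an asymmetric layer contrast does not drag the apex
    bg_lo, bg_hi = at(-4), at(4)
    up = at(-1) - (bg_lo + 3 * (bg_hi - bg_lo) / 8)
    mid = at(0) - (bg_lo + bg_hi) / 2
    down = at(1) - (bg_lo + 5 * (bg_hi - bg_lo) / 8)
    denom = up - 2 * mid + down
    ok = interior & (denom < 0)
    shift = np.zeros_like(refined)
    shift[ok] = 0.5 * (up[ok] - down[ok]) / denom[ok]
    refined += np.clip(shift, -0.5, 0.5)
    return refined


def enforce_ordering(boundaries: np.ndarray, min_sep: float = 1.0) -> np.ndarray:
    """Order-preserving projection onto strictly increasing rows per column.

    Sorts the per-column rows, then pushes each boundary down as needed to
    keep at least ``min_sep`` pixels of separation.
    """
    out = np.sort(np.asarray(boundaries, dtype=float), axis=0)
    for i in range(1, out.shape[0]):
        out[i] = np.maximum(out[i], out[i - 1] + min_sep)
    return out


def apply_correction(
    segmentation: FasciaSegmentation,
    correction: dict[int, np.ndarray] | str | Path,
) -> FasciaSegmentation:
    """Merge operator-supplied replacement polylines into a segmentation.

    ``correction`` maps boundary index (0-3) to a replacement row array on
    the same column range, or is a path to a JSON file
    ``{"boundaries": {"<index>": [rows...]}}``. An empty correction returns
    an equal segmentation. Corrections that break the top-to-bottom
    ordering are rejected with the offending columns named.
    """
    if isinstance(correction, (str, Path)):
        data = json.loads(Path(correction).read_text())
        correction = {int(k): np.asarray(v, dtype=float) for k, v in data.get("boundaries", {}).items()}
    boundaries = segmentation.boundaries.copy()
    if not correction:
        return FasciaSegmentation(
            frame_index=segmentation.frame_index,
            boundaries=boundaries,
            column_range=segmentation.column_range,
            source=segmentation.source,
        )
    for idx, rows in correction.items():
        if not 0 <= idx < N_BOUNDARIES:
            raise ValueError(f"boundary index {idx} out of range 0..{N_BOUNDARIES - 1}")
        rows = np.asarray(rows, dtype=float)
        if rows.shape != (segmentation.n_cols,):
            raise ValueError(
                f"correction for boundary {idx} has length {rows.shape}, "
                f"expected ({segmentation.n_cols},)"
            )
        boundaries[idx] = rows
    # constructor re-validates ordering and names offending columns
    return FasciaSegmentation(
        frame_index=segmentation.frame_index,
        boundaries=boundaries,
        column_range=segmentation.column_range,
        source="corrected",
    )
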