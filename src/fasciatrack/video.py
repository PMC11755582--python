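"""Calibrated B-mode frame stacks and their on-disk formats.

An :class:`UltrasoundVideo` is the package's in-memory container for a
B-mode recording: a ``(n_frames, rows, cols)`` grayscale stack plus the
mm/pixel calibration needed to convert pixel distances into muscle
thickness. Frames are stored row-major with the row index increasing with
axial depth and the column index increasing laterally; this 0-based
convention is shared by every module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile


@dataclass
class UltrasoundVideo:
    """A calibrated stack of 2-D grayscale ultrasound frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Grayscale pixel data. Any numeric dtype; 8-bit unsigned is what the
        TIFF writer emits.
    pixel_spacing : float
        Physical size of one pixel in mm (isotropic).
    frame_rate : float, optional
        Acquisition rate in Hz. Used only to populate the time axis of
        thickness traces.
    """

    frames: np.ndarray
    pixel_spacing: float
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, rows, cols) stack, got ndim={self.frames.ndim}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("video must contain at least one frame")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.frame_rate is not None and not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single frame."""
        return self.frames.shape[1], self.frames.shape[2]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def read_video(
    path: str | Path, pixel_spacing: float, frame_rate: float | None = None
) -> UltrasoundVideo:
    """Load a frame stack from a multi-page TIFF or a directory of PNG frames.

    PNG directories are read in sorted filename order. All frames must share
    one shape; color frames are converted to grayscale by channel averaging.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"video path does not exist: {path}")
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames found in directory: {path}")
        frames = [np.asarray(iio.imread(f)) for f in files]
        frames = [f.mean(axis=2) if f.ndim == 3 else f for f in frames]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"expected a grayscale frame stack in {path}, got shape {stack.shape}")
    return UltrasoundVideo(stack, pixel_spacing=pixel_spacing, frame_rate=frame_rate)


def write_video(video: UltrasoundVideo, path: str | Path) -> Path:
    """Write the stack as an 8-bit multi-page TIFF. Values are clipped to [0, 255]."""
    path = Path(path)
    data = np.clip(video.frames, 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data)
    return path
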