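"""Seeded synthetic B-mode-like videos with known fascia geometry.

The generator renders the lateral abdominal wall as three muscle layers
(OE, OI, TrA, top to bottom) bounded by four bright fasciae, then applies
multiplicative speckle and a small blur. A :class:`ContractionScript`
states the scene exactly — rest and contracted thickness per muscle, a
piecewise-linear ramp/hold/ramp contraction profile, optional in-plane
drift, sinusoidal fascia waviness, and the speckle level — so every
downstream stage (segmentation, tracking, thickness, PAR) can be tested
against analytic ground truth without clinical data.

The image model is deliberately simple: piecewise-constant tissue
intensities, Gaussian-profile fascia ridges, exponential multiplicative
speckle. It emulates the ridge-like fascia echoes and granular noise that
the measurement pipeline must cope with, not ultrasound physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .parstats import compute_par
from .video import UltrasoundVideo, write_video

MUSCLES = ("OE", "OI", "TrA")

# tissue intensities, top to bottom: subcutaneous, OE, OI, TrA, deep
_LAYER_LEVELS = (70.0, 35.0, 45.0, 30.0, 55.0)


@dataclass
class ContractionScript:
    """Deterministic scene description for one synthetic recording.

    Thicknesses are in mm; the contraction profile is piecewise linear:
    rest until ``ramp_up_start``, linear rise to the contracted value at
    ``hold_start``, hold until ``hold_end``, linear fall back to rest at
    ``ramp_down_end``, rest afterwards. Phase boundary indices must be
    strictly increasing and lie within ``[0, n_frames)``.
    """

    n_frames: int = 60
    frame_rate: float = 20.0
    rest_thickness: dict[str, float] = field(
        default_factory=lambda: {"OE": 5.22, "OI": 9.34, "TrA": 4.61}
    )
    contracted_thickness: dict[str, float] = field(
        default_factory=lambda: {"OE": 5.40, "OI": 10.57, "TrA": 5.44}
    )
    ramp_up_start: int = 10
    hold_start: int = 20
    hold_end: int = 40
    ramp_down_end: int = 50
    lateral_drift: float = 0.0  # px per frame
    axial_drift: float = 0.0  # px per frame
    speckle_scale: float = 0.35  # multiplicative noise strength, 0 disables
    blur_sigma: float = 0.8  # px, post-noise Gaussian blur
    static_speckle: bool = False  # one noise field reused on every frame
    fascia_brightness: float = 160.0
    fascia_width: float = 3.0  # px, full width of the Gaussian ridge
    wave_amplitude: float = 0.0  # px, sinusoidal fascia waviness
    wave_length: float = 120.0  # px
    rows: int = 256
    cols: int = 384
    top_depth: float = 30.0  # px, row of the superficial OE fascia at frame 0
    pixel_spacing: float = 0.1  # mm per px

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if not self.frame_rate > 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        for name, table in (
            ("rest_thickness", self.rest_thickness),
            ("contracted_thickness", self.contracted_thickness),
        ):
            for m in MUSCLES:
                if m not in table:
                    raise ValueError(f"{name} missing muscle {m!r}")
                if not table[m] > 0:
                    raise ValueError(f"{name}[{m!r}] must be > 0, got {table[m]}")
        bounds = (self.ramp_up_start, self.hold_start, self.hold_end, self.ramp_down_end)
        if not all(b2 > b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"phase boundaries must be strictly increasing, got {bounds}")
        if bounds[0] < 0 or bounds[-1] >= self.n_frames:
            raise ValueError(
                f"phase boundaries must lie within [0, {self.n_frames}), got {bounds}"
            )
        if not self.wave_length > 0:
            raise ValueError(f"wave_length must be > 0, got {self.wave_length}")

    # -- analytic time courses -------------------------------------------

    def thickness_profile(self, muscle: str) -> np.ndarray:
        """Scripted thickness of one muscle, in mm, for every frame."""
        rest = self.rest_thickness[muscle]
        contracted = self.contracted_thickness[muscle]
        t = np.arange(self.n_frames, dtype=float)
        out = np.full(self.n_frames, rest)
        up = (t >= self.ramp_up_start) & (t < self.hold_start)
        out[up] = rest + (contracted - rest) * (t[up] - self.ramp_up_start) / (
            self.hold_start - self.ramp_up_start
        )
        hold = (t >= self.hold_start) & (t < self.hold_end)
        out[hold] = contracted
        down = (t >= self.hold_end) & (t < self.ramp_down_end)
        out[down] = contracted + (rest - contracted) * (t[down] - self.hold_end) / (
            self.ramp_down_end - self.hold_end
        )
        return out

    def phase_labels(self) -> np.ndarray:
        """Per-frame phase: ``rest``, ``transition`` (ramps) or ``contracted``."""
        t = np.arange(self.n_frames)
        labels = np.full(self.n_frames, "rest", dtype=object)
        labels[(t >= self.ramp_up_start) & (t < self.hold_start)] = "transition"
        labels[(t >= self.hold_start) & (t < self.hold_end)] = "contracted"
        labels[(t >= self.hold_end) & (t < self.ramp_down_end)] = "transition"
        return labels.astype(str)

    def true_par(self) -> float:
        """Closed-form PAR of the scripted rest/contracted thicknesses."""
        r, c = self.rest_thickness, self.contracted_thickness
        return compute_par(
            tra_rest=r["TrA"], oi_rest=r["OI"], oe_rest=r["OE"],
            tra_contracted=c["TrA"], oi_contracted=c["OI"], oe_contracted=c["OE"],
        )


@dataclass
class GroundTruth:
    """Analytic geometry of a generated video.

    ``boundaries`` has shape ``(n_frames, 4, cols)`` with fascia row
    coordinates ordered top to bottom; ``thickness_mm`` has shape
    ``(n_frames, 3)`` in OE/OI/TrA order. By construction the inter-boundary
    pixel distance times ``pixel_spacing`` equals ``thickness_mm`` exactly.
    """

    boundaries: np.ndarray
    thickness_mm: np.ndarray
    phase: np.ndarray
    true_par: float
    pixel_spacing: float

    def trace_frame(self) -> pd.DataFrame:
        """Long-form (frame, muscle, thickness_mm, phase) table."""
        n_frames = self.thickness_mm.shape[0]
        records = []
        for f in range(n_frames):
            for mi, m in enumerate(MUSCLES):
                records.append(
                    {
                        "frame": f,
                        "muscle": m,
                        "thickness_mm": self.thickness_mm[f, mi],
                        "phase": self.phase[f],
                    }
                )
        return pd.DataFrame.from_records(records)


def boundary_rows(script: ContractionScript, frame: int) -> np.ndarray:
    """Fascia row coordinates (4, cols) for one frame of the script."""
    cols = np.arange(script.cols, dtype=float)
    wave = script.wave_amplitude * np.sin(
        2 * np.pi * (cols + script.lateral_drift * frame) / script.wave_length
    )
    top = script.top_depth + script.axial_drift * frame
    rows = np.empty((4, script.cols))
    rows[0] = top + wave
    depth = 0.0
    for i, m in enumerate(MUSCLES):
        depth += script.thickness_profile(m)[frame] / script.pixel_spacing
        rows[i + 1] = top + depth + wave
    return rows


def _material_speckle(
    script: ContractionScript,
    base_noise: np.ndarray,
    margin: int,
    bounds: np.ndarray,
    bounds0: np.ndarray,
    frame: int,
) -> np.ndarray:
    """Sample the tissue-attached speckle field for one frame.

    Fully developed speckle moves with the tissue, so the noise texture
    lives in material coordinates: the coordinates of frame 0. Rows are
    mapped through a per-column piecewise-linear warp anchored at the four
    fascia rows (plus translation sentinels above and below); columns shift
    with the lateral drift.
    """
    rows = np.arange(script.rows, dtype=float)
    mat_rows = np.empty((script.rows, script.cols))
    cm = (np.arange(script.cols, dtype=float) + script.lateral_drift * frame) % script.cols
    # material fascia rows at the shifted columns
    grid = np.arange(script.cols, dtype=float)
    for c in range(script.cols):
        xf = bounds[:, c]
        xm = np.array([np.interp(cm[c], grid, bounds0[b], period=script.cols)
                       for b in range(4)])
        knots_f = np.concatenate([[xf[0] - 500.0], xf, [xf[-1] + 500.0]])
        knots_m = np.concatenate([[xm[0] - 500.0], xm, [xm[-1] + 500.0]])
        mat_rows[:, c] = np.interp(rows, knots_f, knots_m)
    coords = np.vstack(
        [mat_rows.ravel() + margin, np.broadcast_to(cm, mat_rows.shape).ravel()]
    )
    sampled = map_coordinates(base_noise, coords, order=1, mode="grid-wrap")
    return sampled.reshape(script.rows, script.cols)


def _render_frame(script: ContractionScript, bounds: np.ndarray) -> np.ndarray:
    """Noise-free template: piecewise-constant layers + Gaussian fascia ridges."""
    r = np.arange(script.rows, dtype=float)[:, None]
    img = np.full((script.rows, script.cols), _LAYER_LEVELS[0])
    for level, b in zip(_LAYER_LEVELS[1:], bounds):
        img = np.where(r >= b[None, :], level, img)
    # fascia echo replaces the tissue echo at its location (alpha compositing
    # with a Gaussian cross-profile), so the ridge crest sits exactly on the
    # scripted boundary regardless of the layer contrast on either side
    sigma = script.fascia_width / 2.0
    for b in bounds:
        w = np.exp(-((r - b[None, :]) ** 2) / (2 * sigma**2))
        img = img * (1.0 - w) + script.fascia_brightness * w
    return img


def generate_video(
    script: ContractionScript, seed: int
) -> tuple[UltrasoundVideo, GroundTruth]:
    """Render the scripted scene into a speckled frame stack.

    Deterministic for a given ``(script, seed)``. Returns the video and the
    matching analytic :class:`GroundTruth`.
    """
    rng = np.random.default_rng(seed)
    frames = np.empty((script.n_frames, script.rows, script.cols), dtype=np.uint8)
    boundaries = np.empty((script.n_frames, 4, script.cols))
    margin = int(abs(script.axial_drift) * script.n_frames) + 64
    base_noise = None
    if script.speckle_scale > 0:
        base_noise = rng.exponential(
            1.0, size=(script.rows + 2 * margin, script.cols)
        )
    bounds0 = boundary_rows(script, 0)
    for f in range(script.n_frames):
        bounds = boundary_rows(script, f)
        boundaries[f] = bounds
        img = _render_frame(script, bounds)
        if base_noise is not None:
            if script.static_speckle:
                noise = base_noise[margin : margin + script.rows]
            else:
                noise = _material_speckle(script, base_noise, margin, bounds, bounds0, f)
            img = img * (1.0 + script.speckle_scale * (noise - 1.0))
        if script.blur_sigma > 0:
            img = gaussian_filter(img, script.blur_sigma)
        frames[f] = np.clip(img, 0, 255).astype(np.uint8)

    thickness = np.column_stack([script.thickness_profile(m) for m in MUSCLES])
    truth = GroundTruth(
        boundaries=boundaries,
        thickness_mm=thickness,
        phase=script.phase_labels(),
        true_par=script.true_par(),
        pixel_spacing=script.pixel_spacing,
    )
    video = UltrasoundVideo(
        frames, pixel_spacing=script.pixel_spacing, frame_rate=script.frame_rate
    )
    return video, truth


def write_fixture(
    video: UltrasoundVideo,
    truth: GroundTruth,
    directory: str | Path,
    script: ContractionScript | None = None,
    seed: int | None = None,
) -> Path:
    """Write a fixture to disk: frames.tiff + truth.csv + truth.json + manifest.

    Returns the manifest path. The CSV holds the per-frame thickness trace;
    the JSON holds the boundary geometry, the analytic PAR and a script echo.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tiff_path = directory / "frames.tiff"
    csv_path = directory / "truth.csv"
    json_path = directory / "truth.json"
    write_video(video, tiff_path)
    truth.trace_frame().to_csv(csv_path, index=False, float_format="%.6f")
    payload = {
        "true_par": truth.true_par,
        "pixel_spacing": truth.pixel_spacing,
        "boundaries": truth.boundaries.tolist(),
        "phase": truth.phase.tolist(),
    }
    json_path.write_text(json.dumps(payload))
    manifest = {
        "seed": seed,
        "script": asdict(script) if script is not None else None,
        "files": [tiff_path.name, csv_path.name, json_path.name],
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
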