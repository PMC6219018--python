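"""Synthetic labelled recordings for the six sleeping postures.

No public recordings exist for a bedsheet pressure array paired with an
overhead thermal array, so this module simulates them.  A recording is a
posture-dependent deterministic template (upper-body pressure on the 16x10
grid, lower-body heat on the 8x8 grid) subjected to recording-level jitter
(integer translation and small rotation, emulating where and how the
subject lies) and frame-level sensor noise (additive Gaussian plus rare
"ghost" activations that the moving-average filter is meant to reject).

Templates encode the feature-space semantics the classifier relies on:

* supine -- chest and hip contact symmetric left-right and chest-hip;
* prone -- hip-dominant contact (chest-hip balance negative);
* lateral -- narrow contact ridge with the body mass spilling toward the
  facing side (left-right balance signed by side);
* log legs -- one straight warm line along the leg middle axis;
* fetus legs -- a bimodal hook: hip lobe, thin knee bridge on the middle
  axis, and a larger folded shin/foot lobe on the facing side.

Right-side postures are exact left-right mirrors of the left-side
templates.  Every recording carries a ground-truth record (label, trunk
centreline column, waist row, leg middle axis, zero-noise contact masks)
against which the pipeline can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

from .classify import SleepPosture
from .frames_io import (
    BinaryMap,
    FrameSequence,
    GridSpec,
    pressure_grid,
    thermal_grid,
    write_frame_sequence,
)

__all__ = [
    "WEIGHT_CLASSES",
    "AMBIENT_C",
    "BodyModel",
    "JitterSpec",
    "GroundTruth",
    "body_model",
    "pressure_template",
    "thermal_template",
    "generate_recording",
    "generate_examples",
    "generate_dataset",
]

WEIGHT_CLASSES = ("light", "medium", "heavy")  # around 40 / 60 / 80 kg

AMBIENT_C = 24.0  # room-temperature baseline of the thermal array
LEG_DELTA_C = 9.0  # skin reading above ambient for leg cells

# designed template geometry (left-side variants; right postures mirror)
TRUNK_COL = 4  # spine column on the 16x10 pressure grid
WAIST_ROW = 8  # waist row separating chest (rows < 8) from hips (rows > 8)
LEG_AXIS = 3  # leg middle-axis column on the 8x8 thermal grid

# peak contact pressure (kg/cm^2) and footprint width scale per weight class
_WEIGHT_AMP = {"light": 1.2, "medium": 2.0, "heavy": 2.8}
_WEIGHT_WIDTH = {"light": 0.9, "medium": 1.0, "heavy": 1.1}


@dataclass(frozen=True)
class BodyModel:
    """Subject body parameters driving template amplitude and footprint."""

    weight_class: str
    pressure_amp: float  # peak contact pressure, kg/cm^2
    width_scale: float  # multiplier on blob spreads
    leg_delta: float = LEG_DELTA_C  # leg temperature above ambient, deg C

    def __post_init__(self) -> None:
        if self.weight_class not in WEIGHT_CLASSES:
            raise ValueError(f"unknown weight class {self.weight_class!r}")
        if self.pressure_amp <= 0 or self.pressure_amp > 10.0:
            raise ValueError("pressure_amp must lie in (0, 10] kg/cm^2")


def body_model(weight_class: str = "medium") -> BodyModel:
    return BodyModel(
        weight_class=weight_class,
        pressure_amp=_WEIGHT_AMP[weight_class],
        width_scale=_WEIGHT_WIDTH[weight_class],
    )


@dataclass(frozen=True)
class JitterSpec:
    """Recording-level position/orientation jitter and frame-level noise."""

    translation_range: int = 1  # max |dx|, |dy| in cells
    rotation_range_deg: float = 5.0
    noise_sd_pressure: float = 0.2  # kg/cm^2
    noise_sd_thermal: float = 0.5  # deg C
    ghost_rate: float = 0.005  # per-cell per-frame spurious activation

    def __post_init__(self) -> None:
        if self.translation_range < 0 or self.rotation_range_deg < 0:
            raise ValueError("jitter ranges must be >= 0")
        if self.noise_sd_pressure < 0 or self.noise_sd_thermal < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.ghost_rate <= 1.0:
            raise ValueError("ghost_rate must be a probability")

    @classmethod
    def none(cls) -> "JitterSpec":
        """Zero jitter and zero noise (pure templates)."""
        return cls(
            translation_range=0,
            rotation_range_deg=0.0,
            noise_sd_pressure=0.0,
            noise_sd_thermal=0.0,
            ghost_rate=0.0,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Designed geometry and label of one synthetic recording."""

    label: SleepPosture
    weight_class: str
    trunk_col: int
    waist_row: int
    leg_axis: int
    pressure_mask: BinaryMap
    thermal_mask: BinaryMap

    @property
    def cross_point(self) -> tuple[int, int]:
        return (self.waist_row, self.trunk_col)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


def _blob(
    shape: tuple[int, int],
    r0: float,
    c0: float,
    sr: float,
    sc: float,
    amp: float,
    p_row: int = 2,
    p_col: int = 2,
) -> np.ndarray:
    """Separable generalised-Gaussian footprint amp*exp(-|d/s|^p / 2).

    ``p = 2`` gives an ordinary Gaussian; larger even ``p`` gives a
    flat-topped profile with steep edges.  Flat tops matter: the middle
    axis must fall on a plateau of the sensed-point projection, so that
    the axis column is nearest its cluster centre in both position and
    count, not a count-outlier peak.
    """
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(
        -0.5 * np.abs((rr - r0) / sr) ** p_row - 0.5 * np.abs((cc - c0) / sc) ** p_col
    )


# Trunk contact templates.  The body is built from anatomical parts: chest
# and hip/buttock slabs, a flat abdomen bridge over the waist rows (giving
# the vertical projection a flat valley centred on WAIST_ROW), and, for
# lateral postures, a spine ridge plateau at TRUNK_COL with the shoulder/
# arm and flexed-knee bulge on the facing side plus a light trailing-arm
# strip on the back side.  Chest row centre 3.5 and hip centre 12.5 are
# symmetric about the waist row 8.


def pressure_template(posture: SleepPosture, body: BodyModel) -> np.ndarray:
    """Zero-noise upper-body contact-pressure template (16x10, kg/cm^2)."""
    shape = pressure_grid().shape
    a = body.pressure_amp
    w = body.width_scale
    trunk = posture.trunk.value

    abdomen = _blob(shape, WAIST_ROW, TRUNK_COL, 1.4, 1.2 * w, 0.62 * a, p_row=6, p_col=6)
    if trunk == "supine":
        parts = [
            _blob(shape, 3.5, TRUNK_COL, 1.4 * w, 2.2 * w, a),
            _blob(shape, 12.5, TRUNK_COL, 1.4 * w, 2.2 * w, a),
            abdomen,
        ]
    elif trunk == "prone":
        # chest as in supine; hips/thighs broader and reaching further
        # toward the feet, so the chest-hip balance goes negative
        parts = [
            _blob(shape, 3.5, TRUNK_COL, 1.4 * w, 2.2 * w, a),
            _blob(shape, 12.7, TRUNK_COL, 1.7 * w, 3.5 * w, 1.05 * a),
            abdomen,
        ]
    else:
        # side lying: spine ridge plateau at the trunk column, body bulge
        # (shoulder, arm, flexed knees) on the facing side, trailing arm
        # lightly touching on the back side
        parts = [
            _blob(shape, 3.5, TRUNK_COL, 1.3, 1.45 * w, 1.05 * a, p_col=6),
            _blob(shape, 12.5, TRUNK_COL, 1.3, 1.45 * w, 1.05 * a, p_col=6),
            _blob(shape, WAIST_ROW, TRUNK_COL, 1.4, 1.45 * w, 0.62 * a, p_row=6, p_col=6),
            _blob(shape, 3.5, 7.0, 1.3, 1.45 * w, 0.55 * a, p_col=6),
            _blob(shape, 12.5, 7.0, 1.3, 1.45 * w, 0.55 * a, p_col=6),
            _blob(shape, 4.2, 1.0, 1.1, 0.55, 0.6 * a),
        ]
    template = np.clip(np.sum(parts, axis=0), 0.0, 10.0)
    if trunk == "right_lateral":
        template = template[:, ::-1]
    return template


def _mark(cells: list[tuple[int, int]], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    for r, c in cells:
        out[r, c] = 1.0
    return out


def thermal_template(posture: SleepPosture, body: BodyModel) -> np.ndarray:
    """Zero-noise lower-body temperature template (8x8, deg C)."""
    shape = thermal_grid().shape
    a = LEG_AXIS
    if posture in (SleepPosture.SUPINE, SleepPosture.PRONE):
        # two parallel straight legs flanking the axis, thighs adjoining it
        cells = [(r, a - 1) for r in range(8)] + [(r, a + 1) for r in range(8)]
        cells += [(r, a) for r in range(3)]
    elif posture.legs is not None and posture.legs.value == "log":
        # stacked straight legs: one warm line on the axis, wider at the hips
        cells = [(r, a) for r in range(8)] + [(0, a - 1), (0, a + 1)]
    else:
        # fetus: hips/thighs on one column, a short knee bridge one column
        # toward the facing side (the middle axis lands on the knees), and
        # the folded shins and feet as a taller double column beyond it
        cells = [(r, a) for r in range(4)]  # hip + thigh
        cells += [(3, a + 1), (4, a + 1)]  # knees
        cells += [(r, a + 2) for r in range(2, 7)]  # folded shins
        cells += [(r, a + 3) for r in range(2, 7)]  # feet
    template = AMBIENT_C + body.leg_delta * _mark(cells, shape)
    if posture.trunk.value == "right_lateral":
        template = template[:, ::-1]
    return template


# ---------------------------------------------------------------------------
# Jitter and noise
# ---------------------------------------------------------------------------


def _translate(template: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(template, fill)
    rows, cols = template.shape
    if abs(dy) >= rows or abs(dx) >= cols:
        return out
    src_r = slice(max(0, -dy), min(rows, rows - dy))
    src_c = slice(max(0, -dx), min(cols, cols - dx))
    dst_r = slice(max(0, dy), min(rows, rows + dy))
    dst_c = slice(max(0, dx), min(cols, cols + dx))
    out[dst_r, dst_c] = template[src_r, src_c]
    return out


def _rotate(
    template: np.ndarray, angle_deg: float, center: tuple[float, float], fill: float
) -> np.ndarray:
    """Nearest-cell rotation about ``center`` (row, col)."""
    if angle_deg == 0.0:
        return template
    theta = math.radians(angle_deg)
    rows, cols = template.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr, dc = rr - center[0], cc - center[1]
    # inverse mapping: sample the source at the back-rotated coordinate
    src_r = np.rint(center[0] + dr * math.cos(theta) - dc * math.sin(theta)).astype(int)
    src_c = np.rint(center[1] + dr * math.sin(theta) + dc * math.cos(theta)).astype(int)
    inside = (src_r >= 0) & (src_r < rows) & (src_c >= 0) & (src_c < cols)
    out = np.full_like(template, fill)
    out[inside] = template[src_r[inside], src_c[inside]]
    return out


def _mirror_col(col: int, cols: int) -> int:
    return cols - 1 - col


def generate_recording(
    posture: SleepPosture,
    body: BodyModel,
    jitter: JitterSpec,
    n_frames: int = 12,
    rng: np.random.Generator | int | None = None,
) -> tuple[FrameSequence, FrameSequence, GroundTruth]:
    """Simulate one recording: pressure frames, thermal frames, ground truth.

    The jittered template is fixed for the recording (the subject holds the
    posture); each frame adds independent Gaussian noise and ghost
    activations.  Deterministic for a given seed/generator.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(rng)

    p_grid, t_grid = pressure_grid(), thermal_grid()
    p_template = pressure_template(posture, body)
    t_template = thermal_template(posture, body)

    right_side = posture.trunk.value == "right_lateral"
    # fetus recordings: the leg middle axis sits on the knee column, one
    # column toward the facing side of the hip/thigh line
    leg_axis = LEG_AXIS + 1 if (posture.legs and posture.legs.value == "fetus") else LEG_AXIS
    trunk_col = _mirror_col(TRUNK_COL, p_grid.cols) if right_side else TRUNK_COL
    leg_axis = _mirror_col(leg_axis, t_grid.cols) if right_side else leg_axis

    T = jitter.translation_range
    dxp, dyp = int(rng.integers(-T, T + 1)), int(rng.integers(-T, T + 1))
    dxt, dyt = int(rng.integers(-T, T + 1)), int(rng.integers(-T, T + 1))
    angle = float(rng.uniform(-jitter.rotation_range_deg, jitter.rotation_range_deg))

    p_template = _translate(p_template, dyp, dxp, fill=0.0)
    t_template = _translate(t_template, dyt, dxt, fill=AMBIENT_C)
    trunk_col, waist_row = trunk_col + dxp, WAIST_ROW + dyp
    leg_axis = leg_axis + dxt

    p_template = _rotate(p_template, angle, center=(waist_row, trunk_col), fill=0.0)
    t_template = _rotate(
        t_template, angle, center=(t_grid.rows / 2 - 0.5, leg_axis), fill=AMBIENT_C
    )

    if not (0 <= trunk_col < p_grid.cols and 0 <= waist_row < p_grid.rows):
        raise ValueError("jitter pushed the trunk off the pressure grid")
    if not 0 <= leg_axis < t_grid.cols:
        raise ValueError("jitter pushed the legs off the thermal grid")
    if p_template.max() == 0.0:
        raise ValueError("jitter pushed the body fully off the pressure grid")

    # ambient-relative thermal contact mask mirrors the preprocessing rule
    truth = GroundTruth(
        label=posture,
        weight_class=body.weight_class,
        trunk_col=trunk_col,
        waist_row=waist_row,
        leg_axis=leg_axis,
        pressure_mask=BinaryMap(grid=p_grid, cells=(p_template > 0.5).astype(int)),
        thermal_mask=BinaryMap(
            grid=t_grid,
            cells=(t_template > np.median(t_template) + 2.0).astype(int),
        ),
    )

    def frames(template: np.ndarray, sd: float, ghost_value: float, lo, hi) -> np.ndarray:
        out = np.empty((n_frames,) + template.shape)
        for i in range(n_frames):
            frame = template + rng.normal(0.0, sd, template.shape) if sd > 0 else template.copy()
            if jitter.ghost_rate > 0:
                ghosts = rng.random(template.shape) < jitter.ghost_rate
                frame = np.where(ghosts, ghost_value, frame)
            out[i] = np.clip(frame, lo, hi)
        return out

    pressure_seq = FrameSequence.from_array(
        p_grid, frames(p_template, jitter.noise_sd_pressure, 2.0, 0.0, 10.0)
    )
    thermal_seq = FrameSequence.from_array(
        t_grid,
        frames(t_template, jitter.noise_sd_thermal, AMBIENT_C + LEG_DELTA_C, -40.0, 80.0),
    )
    return pressure_seq, thermal_seq, truth


def generate_examples(
    n_per_class: int,
    jitter: JitterSpec | None = None,
    seed: int = 0,
    n_frames: int = 12,
    weight_classes: tuple[str, ...] = WEIGHT_CLASSES,
) -> Iterator[tuple[FrameSequence, FrameSequence, GroundTruth]]:
    """Yield a class-balanced stream of recordings, cycling weight classes."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    jitter = JitterSpec() if jitter is None else jitter
    rng = np.random.default_rng(seed)
    for posture in SleepPosture:
        for i in range(n_per_class):
            body = body_model(weight_classes[i % len(weight_classes)])
            yield generate_recording(posture, body, jitter, n_frames=n_frames, rng=rng)


def generate_dataset(
    out_dir: str | Path,
    n_per_class: int,
    jitter: JitterSpec | None = None,
    seed: int = 0,
    n_frames: int = 12,
) -> Path:
    """Write a labelled dataset (frame files + JSON manifest); return manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for idx, (p_seq, t_seq, truth) in enumerate(
        generate_examples(n_per_class, jitter, seed, n_frames)
    ):
        stem = f"rec{idx:04d}_{truth.label.value}"
        p_path = out_dir / f"{stem}_pressure.csv"
        t_path = out_dir / f"{stem}_thermal.csv"
        write_frame_sequence(p_seq, p_path)
        write_frame_sequence(t_seq, t_path)
        records.append(
            {
                "id": stem,
                "label": truth.label.value,
                "weight_class": truth.weight_class,
                "pressure": p_path.name,
                "thermal": t_path.name,
                "trunk_col": truth.trunk_col,
                "waist_row": truth.waist_row,
                "leg_axis": truth.leg_axis,
            }
        )
    manifest = out_dir / "manifest.json"
    manifest.write_text(
        json.dumps({"seed": seed, "n_per_class": n_per_class, "records": records}, indent=1)
    )
    return manifest
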