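"""Domain types, grid conventions, frame file I/O and run configuration.

Grid conventions (global, relied on by every stage):

* Row 0 is the **head end** of the sensing surface.
* Column 0 is the **subject's right side** as seen from above the supine
  subject (image-left in the figures).
* Coordinates are 0-based and row-major.

Two sensing roles exist: a ``pressure`` bedsheet array (default 16 rows by
10 columns, readings in kg/cm^2, full scale 10) under the upper body, and a
``thermal`` infrared array (default 8x8, readings in degrees Celsius)
imaging the lower body from above.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "GridSpec",
    "SensorFrame",
    "FrameSequence",
    "BinaryMap",
    "FCMConfig",
    "KNNConfig",
    "RunConfig",
    "pressure_grid",
    "thermal_grid",
    "read_frame_sequence",
    "write_frame_sequence",
    "load_config",
    "get_logger",
]

PRESSURE_FULL_SCALE = 10.0  # kg/cm^2, sensor saturation value


def get_logger(name: str = "somnapose") -> logging.Logger:
    """Structured ``level | stage | message`` logger writing to stderr."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s | %(name)s | %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass(frozen=True)
class GridSpec:
    """Geometry and role of one sensor array."""

    rows: int
    cols: int
    role: str  # "pressure" or "thermal"

    def __post_init__(self) -> None:
        if self.role not in ("pressure", "thermal"):
            raise ValueError(f"unknown grid role {self.role!r}")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)


def pressure_grid(rows: int = 16, cols: int = 10) -> GridSpec:
    return GridSpec(rows=rows, cols=cols, role="pressure")


def thermal_grid(rows: int = 8, cols: int = 8) -> GridSpec:
    return GridSpec(rows=rows, cols=cols, role="thermal")


@dataclass(frozen=True)
class SensorFrame:
    """One time-stamped matrix of raw readings from a sensor array."""

    grid: GridSpec
    t: int
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(
                f"frame shape {values.shape} does not match grid {self.grid.shape}"
            )
        if self.t < 0:
            raise ValueError("sample index t must be >= 0")
        if self.grid.role == "pressure":
            if np.any(values < 0) or np.any(values > PRESSURE_FULL_SCALE):
                raise ValueError(
                    f"pressure values must lie in [0, {PRESSURE_FULL_SCALE}] kg/cm^2"
                )
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class FrameSequence:
    """Ordered frames from one array with strictly increasing sample index."""

    grid: GridSpec
    frames: tuple[SensorFrame, ...]

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise ValueError("a frame sequence must contain at least one frame")
        for f in frames:
            if f.grid != self.grid:
                raise ValueError("all frames must share the sequence grid")
        ts = [f.t for f in frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("sample indices must be strictly increasing")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SensorFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> SensorFrame:
        return self.frames[i]

    def stack(self) -> np.ndarray:
        """All frames as one (n, rows, cols) array, in sample order."""
        return np.stack([f.values for f in self.frames])

    @classmethod
    def from_array(cls, grid: GridSpec, values: np.ndarray) -> "FrameSequence":
        """Build a sequence from an (n, rows, cols) array, t = 0..n-1."""
        values = np.asarray(values, dtype=float)
        return cls(
            grid=grid,
            frames=tuple(
                SensorFrame(grid=grid, t=i, values=v) for i, v in enumerate(values)
            ),
        )


@dataclass(frozen=True)
class BinaryMap:
    """Thresholded 0/1 map of sensed points on one grid."""

    grid: GridSpec
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=int)
        if cells.shape != self.grid.shape:
            raise ValueError(
                f"map shape {cells.shape} does not match grid {self.grid.shape}"
            )
        if not np.isin(cells, (0, 1)).all():
            raise ValueError("binary map entries must be 0 or 1")
        object.__setattr__(self, "cells", cells)

    @property
    def total(self) -> int:
        return int(self.cells.sum())

    def mirrored(self) -> "BinaryMap":
        """Left-right mirror (subject's right <-> left)."""
        return BinaryMap(grid=self.grid, cells=self.cells[:, ::-1].copy())


@dataclass(frozen=True)
class FCMConfig:
    """Fuzzy c-means settings for middle-axis clustering."""

    m: float = 2.0  # fuzzifier, > 1
    epsilon: float = 1e-5  # stop when |dA| between iterations < epsilon
    max_iter: int = 200
    n_clusters: int = 3  # background / foreground / background

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("fcm.m must be > 1")
        if self.epsilon <= 0:
            raise ValueError("fcm.epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("fcm.max_iter must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("fcm.n_clusters must be >= 1")


@dataclass(frozen=True)
class KNNConfig:
    """Distance-weighted k-NN settings (weight = 1 / d^weight_exponent)."""

    k: int = 5
    weight_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("knn.k must be >= 1")
        if self.weight_exponent <= 0:
            raise ValueError("knn.weight_exponent must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with validated defaults.

    ``maf_window`` is the moving-average length N (default 10 samples).
    ``pressure_threshold`` is an absolute sensed-point threshold in kg/cm^2.
    ``thermal_offset`` is a relative threshold: a thermal cell is sensed when
    it exceeds the per-frame median (the ambient estimate) by this many
    degrees Celsius.
    """

    maf_window: int = 10
    pressure_threshold: float = 0.5
    thermal_offset: float = 2.0
    fcm: FCMConfig = field(default_factory=FCMConfig)
    knn: KNNConfig = field(default_factory=KNNConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maf_window < 1:
            raise ValueError("maf_window must be >= 1")
        if not np.isfinite(self.pressure_threshold):
            raise ValueError("pressure_threshold must be finite")
        if not np.isfinite(self.thermal_offset):
            raise ValueError("thermal_offset must be finite")


# ---------------------------------------------------------------------------
# Frame files: blank-line separated blocks, one frame per block, each block a
# "# t=<index>" header followed by comma-separated rows; '#' starts a comment.
# ---------------------------------------------------------------------------


def write_frame_sequence(seq: FrameSequence, path: str | Path) -> Path:
    """Write a frame sequence as a delimited-text file; lossless round trip.

    Values are written with ``repr`` so that reading the file back
    reproduces every float bit-exactly.
    """
    path = Path(path)
    lines: list[str] = [f"# somnapose frames role={seq.grid.role} "
                        f"rows={seq.grid.rows} cols={seq.grid.cols}"]
    for frame in seq:
        lines.append(f"# t={frame.t}")
        for row in frame.values:
            lines.append(",".join(repr(float(v)) for v in row))
        lines.append("")
    path.write_text("\n".join(lines))
    return path


def read_frame_sequence(path: str | Path, grid: GridSpec) -> FrameSequence:
    """Read a frame file written by :func:`write_frame_sequence`.

    Raises ``ValueError`` with the offending record/row on malformed shapes
    and with cell coordinates on non-numeric cells.
    """
    path = Path(path)
    frames: list[SensorFrame] = []
    block: list[list[float]] = []
    t_header: int | None = None
    next_t = 0

    def flush(lineno: int) -> None:
        nonlocal block, t_header, next_t
        if not block:
            t_header = None
            return
        mat = np.array(block, dtype=float)
        if mat.shape != grid.shape:
            raise ValueError(
                f"{path}: record ending at line {lineno} has shape {mat.shape}, "
                f"expected {grid.shape}"
            )
        t = t_header if t_header is not None else next_t
        frames.append(SensorFrame(grid=grid, t=t, values=mat))
        next_t = t + 1
        block = []
        t_header = None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                if line[1:].strip().startswith("t="):
                    flush(lineno)
                    t_header = int(line.split("=", 1)[1])
                continue
            if not line:
                flush(lineno)
                continue
            cells = line.split(",")
            row: list[float] = []
            for j, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell at line {lineno}, column {j}: "
                        f"{cell!r}"
                    ) from None
            block.append(row)
        flush(lineno=-1)

    if not frames:
        raise ValueError(f"{path}: no frames found")
    return FrameSequence(grid=grid, frames=tuple(frames))


# ---------------------------------------------------------------------------
# Run configuration files (YAML or JSON; YAML is a superset of JSON here).
# ---------------------------------------------------------------------------

_CONFIG_ALIASES = {"N": "maf_window", "thermal_threshold": "thermal_offset"}


def config_from_mapping(doc: dict | None) -> RunConfig:
    """Build a validated RunConfig from a (possibly partial) mapping."""
    doc = dict(doc or {})
    for alias, target in _CONFIG_ALIASES.items():
        if alias in doc:
            doc[target] = doc.pop(alias)
    fcm_doc = doc.pop("fcm", {}) or {}
    knn_doc = doc.pop("knn", {}) or {}
    unknown = set(doc) - {
        "maf_window", "pressure_threshold", "thermal_offset", "seed"
    }
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    try:
        fcm = FCMConfig(**fcm_doc)
        knn = KNNConfig(**knn_doc)
        return RunConfig(fcm=fcm, knn=knn, **doc)
    except TypeError as exc:
        raise ValueError(f"invalid config: {exc}") from None


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration, filling defaults and validating."""
    doc = yaml.safe_load(Path(path).read_text())
    if doc is not None and not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(doc).__name__}")
    return config_from_mapping(doc)
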