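"""Temporal denoising and sensed-point thresholding.

Each cell of a raw frame sequence is smoothed with a moving-average filter
(MAF) over the N most recent samples,

    MAF_t = (x_t + x_{t-1} + ... + x_{t-N+1}) / N,

which suppresses random temporal noise such as mattress pressure flutter.
The smoothed frame is then binarised: a cell becomes a "sensed point" (1)
when its value is strictly greater than the detection threshold, else 0.
The pressure stream uses an absolute threshold in kg/cm^2; the thermal
stream uses an ambient-relative threshold (per-frame median + offset) so
that it is insensitive to the room temperature baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames_io import BinaryMap, FrameSequence, GridSpec, RunConfig

__all__ = [
    "SmoothedFrame",
    "moving_average",
    "threshold_frame",
    "thermal_threshold_value",
    "preprocess_recording",
]


@dataclass(frozen=True)
class SmoothedFrame:
    """Per-cell moving-average output at one sample index."""

    grid: GridSpec
    t: int
    values: np.ndarray


def moving_average(seq: FrameSequence, N: int, t: int) -> SmoothedFrame:
    """Moving-average filter over the up-to-N most recent samples at ``t``.

    During warm-up (t < N-1) the mean is taken over the t+1 samples that
    exist, so the filter is defined from the first frame onward.
    """
    if N < 1:
        raise ValueError("moving-average window N must be >= 1")
    if not 0 <= t < len(seq):
        raise IndexError(f"sample index {t} out of range for sequence of length {len(seq)}")
    start = max(0, t - N + 1)
    window = seq.stack()[start : t + 1]
    return SmoothedFrame(grid=seq.grid, t=t, values=window.mean(axis=0))


def threshold_frame(frame: SmoothedFrame, tau: float) -> BinaryMap:
    """Binarise: cell = 1 iff value > tau (strictly), else 0."""
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    return BinaryMap(grid=frame.grid, cells=(frame.values > tau).astype(int))


def thermal_threshold_value(frame: SmoothedFrame, offset: float) -> float:
    """Ambient-relative thermal threshold: per-frame median + offset (deg C)."""
    return float(np.median(frame.values)) + offset


def preprocess_recording(
    pressure: FrameSequence | None,
    thermal: FrameSequence | None,
    cfg: RunConfig,
    t: int | None = None,
) -> tuple[BinaryMap | None, BinaryMap | None]:
    """Smooth and threshold both streams into sensed-point maps.

    ``t`` defaults to the last sample of each stream.  Either stream may be
    ``None``; the corresponding output is then ``None`` (graceful
    degradation when one sensor is missing).
    """
    if pressure is None and thermal is None:
        raise ValueError("at least one of the pressure/thermal streams is required")

    pressure_map = None
    if pressure is not None:
        tp = len(pressure) - 1 if t is None else t
        smoothed = moving_average(pressure, cfg.maf_window, tp)
        pressure_map = threshold_frame(smoothed, cfg.pressure_threshold)

    thermal_map = None
    if thermal is not None:
        tt = len(thermal) - 1 if t is None else t
        smoothed = moving_average(thermal, cfg.maf_window, tt)
        tau = thermal_threshold_value(smoothed, cfg.thermal_offset)
        thermal_map = threshold_frame(smoothed, tau)

    return pressure_map, thermal_map
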