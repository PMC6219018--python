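"""Sensor-deployment analytics: resolution, sensing gap, detection threshold.

For a square lattice of disk-shaped pressure sensors, sparser deployment
opens gaps in which a small body part can rest without touching any
sensor.  Three quantities characterise a deployment:

* **spatial sensing resolution** -- sensing points per square metre of
  coverage, ``(n_rows * n_cols) / (coverage_w * coverage_h)``;
* **sensing gap** -- edge-to-edge distance between adjacent sensor disks,
  ``pitch - 2 * sensor_radius`` (an infrared array images contiguous
  pixels, so it has no sensing gap);
* **signal detection threshold max(A_u)** -- the area of the largest body
  part that can evade every sensor: a circle centred in a sensing grid
  cell that touches, but does not overlap, the four corner sensor disks,

      max(A_u) = pi * (pitch * sqrt(2)/2 - sensor_radius)^2 .

Smaller max(A_u) is better.  For the overhead infrared array the
detectability limit is not geometric but empirical (shank/finger
experiments); it is stored as the constant
:data:`INFRARED_DETECTION_THRESHOLD_CM2`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DeploymentSpec",
    "INFRARED_DETECTION_THRESHOLD_CM2",
    "sparse_pressure_lattice",
    "grid_eye_deployment",
    "spatial_resolution",
    "sensing_gap",
    "max_undetectable_area",
    "compare_deployments",
]

# Empirical detectability limit of the 8x8 infrared array: a body part of
# ~25 cm^2 within one sensing grid is reliably detected, smaller ones not.
INFRARED_DETECTION_THRESHOLD_CM2 = 25.0


@dataclass(frozen=True)
class DeploymentSpec:
    """Geometry of one sensor-array deployment."""

    n_rows: int
    n_cols: int
    coverage_w: float  # metres
    coverage_h: float  # metres
    sensor_radius: float = 0.0  # metres; disk sensors of a pressure lattice
    kind: str = "pressure_lattice"  # or "infrared_array"

    def __post_init__(self) -> None:
        if self.kind not in ("pressure_lattice", "infrared_array"):
            raise ValueError(f"unknown deployment kind {self.kind!r}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("sensor counts must be >= 1")
        if self.coverage_w <= 0 or self.coverage_h <= 0:
            raise ValueError("coverage must be positive")
        if self.sensor_radius < 0:
            raise ValueError("sensor_radius must be >= 0")
        if self.kind == "pressure_lattice" and self.pitch <= 2 * self.sensor_radius:
            raise ValueError("pitch must exceed the sensor diameter")

    @property
    def n_sensors(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pitch(self) -> float:
        """Centre-to-centre sensor spacing along the width, metres."""
        return self.coverage_w / self.n_cols


def sparse_pressure_lattice() -> DeploymentSpec:
    """The 7x7 disk-sensor lattice over 0.875 m x 0.875 m used for comparison.

    The sensor radius follows from the printed pitch (0.875/7 = 0.125 m)
    and the printed 0.1 m sensing gap: r = (pitch - gap) / 2 = 0.0125 m.
    """
    return DeploymentSpec(
        n_rows=7,
        n_cols=7,
        coverage_w=0.875,
        coverage_h=0.875,
        sensor_radius=0.0125,
        kind="pressure_lattice",
    )


def grid_eye_deployment() -> DeploymentSpec:
    """The 8x8 infrared array imaging a 1 m x 1 m area from above."""
    return DeploymentSpec(
        n_rows=8, n_cols=8, coverage_w=1.0, coverage_h=1.0, kind="infrared_array"
    )


def spatial_resolution(spec: DeploymentSpec) -> float:
    """Sensing points (or pixels) per square metre of coverage."""
    return spec.n_sensors / (spec.coverage_w * spec.coverage_h)


def sensing_gap(spec: DeploymentSpec) -> float | None:
    """Edge-to-edge distance between adjacent sensors, metres.

    Returns ``None`` for an infrared array: adjoining pixels leave no
    sensing gap.
    """
    if spec.kind == "infrared_array":
        return None
    return spec.pitch - 2 * spec.sensor_radius


def max_undetectable_area(spec: DeploymentSpec, pi_value: float = math.pi) -> float:
    """Signal detection threshold max(A_u) of a pressure lattice, in cm^2.

    Area of the largest circle centred in the square sensing grid that
    touches but does not overlap the four corner sensor disks.  The
    ``pi_value`` parameter exists because published figures for this
    quantity are sometimes computed with pi rounded to 3.14.
    """
    if spec.kind != "pressure_lattice":
        raise ValueError("max_undetectable_area applies to pressure lattices only")
    radius_m = spec.pitch * math.sqrt(2.0) / 2.0 - spec.sensor_radius
    return pi_value * radius_m**2 * 1e4  # m^2 -> cm^2


def compare_deployments(a: DeploymentSpec, b: DeploymentSpec) -> dict:
    """Side-by-side comparison record of two deployments.

    Tabulates sensor count, spatial resolution, sensing gap and the signal
    detection threshold (geometric for a pressure lattice, the empirical
    constant for an infrared array); smaller detection threshold is better.
    """

    def describe(spec: DeploymentSpec) -> dict:
        if spec.kind == "pressure_lattice":
            threshold = max_undetectable_area(spec)
        else:
            threshold = INFRARED_DETECTION_THRESHOLD_CM2
        gap = sensing_gap(spec)
        return {
            "kind": spec.kind,
            "n_sensors": spec.n_sensors,
            "spatial_resolution_per_m2": spatial_resolution(spec),
            "sensing_gap_m": gap,  # None -> not applicable
            "detection_threshold_cm2": threshold,
        }

    rec_a, rec_b = describe(a), describe(b)
    better = "a" if rec_a["detection_threshold_cm2"] < rec_b["detection_threshold_cm2"] else "b"
    if rec_a["detection_threshold_cm2"] == rec_b["detection_threshold_cm2"]:
        better = "tie"
    return {"a": rec_a, "b": rec_b, "better_detection_threshold": better}
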