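"""Body-part segmentation and symmetry features.

The trunk middle point cuts the pressure sensed-point map into four
quadrants -- right-chest (C_R), left-chest (C_L), right-hip (H_R) and
left-hip (H_L) -- and the leg middle axis splits the thermal map into
right-leg (L_R), left-leg (L_L) and on-axis (L_MAC) cells.  "Right/left"
are the subject's sides: column 0 is the subject's right, the chest is the
rows nearer the head end (row 0).  Cells lying exactly on a trunk middle
axis belong to no quadrant; thermal cells on the leg axis are L_MAC.

The four symmetry features are

    T_D-RL = (C_R + H_R) - (C_L + H_L)      trunk right-left balance
    T_D-CH = (C_R + C_L) - (H_R + H_L)      trunk chest-hip balance
    L_D-RL = |L_R - L_L|                    leg right-left asymmetry
    L_MAC  = on-axis leg sensed points      leg straightness

Supine sits near the origin of (T_D-RL, T_D-CH); prone has negative
T_D-CH; left/right lateral have negative/positive T_D-RL.  Straight (log)
legs give large L_MAC and small L_D-RL; curled (fetus) legs the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .frames_io import BinaryMap
from .fcm_segment import MiddleAxes

__all__ = [
    "QuadrantCounts",
    "LegCounts",
    "PostureFeatures",
    "segment_trunk",
    "segment_legs",
    "compute_features",
]


@dataclass(frozen=True)
class QuadrantCounts:
    C_R: int
    C_L: int
    H_R: int
    H_L: int

    def __post_init__(self) -> None:
        if min(self.C_R, self.C_L, self.H_R, self.H_L) < 0:
            raise ValueError("quadrant counts must be non-negative")


@dataclass(frozen=True)
class LegCounts:
    L_L: int
    L_R: int
    L_MAC: int

    def __post_init__(self) -> None:
        if min(self.L_L, self.L_R, self.L_MAC) < 0:
            raise ValueError("leg counts must be non-negative")


@dataclass(frozen=True)
class PostureFeatures:
    T_D_RL: int
    T_D_CH: int
    L_D_RL: int
    L_MAC: int

    @property
    def trunk(self) -> tuple[float, float]:
        return (float(self.T_D_RL), float(self.T_D_CH))

    @property
    def legs(self) -> tuple[float, float]:
        return (float(self.L_D_RL), float(self.L_MAC))


def segment_trunk(bm: BinaryMap, axes: MiddleAxes) -> QuadrantCounts:
    """Count sensed points in the four trunk quadrants around the cross point.

    Strict inequalities: cells on either middle axis are excluded from all
    four quadrants.
    """
    waist_row, trunk_col = axes.cross_point
    if not (0 <= waist_row < bm.grid.rows and 0 <= trunk_col < bm.grid.cols):
        raise ValueError(f"cross point {axes.cross_point} outside grid {bm.grid.shape}")
    cells = bm.cells
    chest = cells[:waist_row, :]  # rows strictly above the waist (head side)
    hips = cells[waist_row + 1 :, :]
    return QuadrantCounts(
        C_R=int(chest[:, :trunk_col].sum()),
        C_L=int(chest[:, trunk_col + 1 :].sum()),
        H_R=int(hips[:, :trunk_col].sum()),
        H_L=int(hips[:, trunk_col + 1 :].sum()),
    )


def segment_legs(bm: BinaryMap, axis: int) -> LegCounts:
    """Partition thermal sensed points into right/left of and on the leg axis.

    The partition is exhaustive: L_L + L_R + L_MAC equals the total number
    of sensed points.
    """
    if not 0 <= axis < bm.grid.cols:
        raise ValueError(f"leg axis {axis} outside grid with {bm.grid.cols} columns")
    cells = bm.cells
    return LegCounts(
        L_R=int(cells[:, :axis].sum()),
        L_L=int(cells[:, axis + 1 :].sum()),
        L_MAC=int(cells[:, axis].sum()),
    )


def compute_features(q: QuadrantCounts, legs: LegCounts) -> PostureFeatures:
    """Exact integer symmetry features from the segmented counts."""
    return PostureFeatures(
        T_D_RL=(q.C_R + q.H_R) - (q.C_L + q.H_L),
        T_D_CH=(q.C_R + q.C_L) - (q.H_R + q.H_L),
        L_D_RL=abs(legs.L_R - legs.L_L),
        L_MAC=legs.L_MAC,
    )
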