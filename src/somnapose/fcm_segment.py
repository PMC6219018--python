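"""Histogram projection and fuzzy c-means middle-axis localisation.

A binary sensed-point map is projected onto the horizontal axis (per-column
counts) and the vertical axis (per-row counts).  Each occupied positioning
index i becomes a 2-D point x_i = (position, count), and the points are
soft-clustered by fuzzy c-means (FCM), minimising

    A = sum_i sum_k u_ik^m ||x_i - c_k||^2,      sum_k u_ik = 1,

with the Euclidean distance ||x_i - c_k|| = sqrt((x_iP - c_kP)^2 +
(x_iN - c_kN)^2) taken over the (position, count) pair.  With c = 3
clusters the two outer clusters are background (flanks of the body support)
and the middle cluster is the foreground mapped to the trunk (horizontal
projection), the waist (vertical projection of the pressure map) or the leg
mass (thermal map).  The positioning index with maximal membership in the
middle cluster is the **middle axis**; the trunk's horizontal and vertical
middle axes cross at the **middle point**, the key to quadrant
segmentation.  Clustering on the projection rather than on raw cell
coordinates makes the axis robust to where on the bed, and at what small
rotation, the subject lies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames_io import BinaryMap, RunConfig

__all__ = [
    "Projection",
    "AxisClustering",
    "MiddleAxes",
    "project_histogram",
    "evenly_spaced_init",
    "fcm_cluster",
    "find_middle_axis",
    "find_trunk_middle_point",
    "find_leg_middle_axis",
]


@dataclass(frozen=True)
class Projection:
    """Sensed-point counts along one axis of a binary map."""

    axis: str  # "horizontal" (per-column) or "vertical" (per-row)
    counts: np.ndarray

    def occupied(self) -> np.ndarray:
        """Positioning indexes with at least one sensed point."""
        return np.flatnonzero(self.counts > 0)

    def points(self) -> np.ndarray:
        """(n, 2) array of (position, count) pairs over occupied indexes."""
        idx = self.occupied()
        return np.column_stack([idx, self.counts[idx]]).astype(float)


@dataclass(frozen=True)
class AxisClustering:
    """Result of one FCM run over (position, count) points.

    ``centers`` rows are (position, count) cluster centres; ``U`` is the
    n-by-c membership matrix with rows summing to 1; ``objective_trace`` is
    the value of A after each iteration (non-increasing); ``labels`` is the
    defuzzified (argmax-membership) cluster of each point.
    """

    c: int
    m: float
    points: np.ndarray
    centers: np.ndarray
    U: np.ndarray
    objective_trace: np.ndarray
    labels: np.ndarray
    # membership matrix after each iteration, for auditing the invariant
    # that rows sum to 1 throughout the run (instances are tiny)
    membership_trace: tuple[np.ndarray, ...] = ()


@dataclass(frozen=True)
class MiddleAxes:
    """Trunk middle axes: column (trunk line), row (waist), and cross point."""

    horizontal_axis: int
    vertical_axis: int
    cross_point: tuple[int, int]  # (row, col) = (vertical_axis, horizontal_axis)


def project_histogram(bm: BinaryMap, axis: str) -> Projection:
    """Project sensed points onto one axis.

    ``horizontal`` counts per column; ``vertical`` counts per row.
    """
    if axis == "horizontal":
        counts = bm.cells.sum(axis=0)
    elif axis == "vertical":
        counts = bm.cells.sum(axis=1)
    else:
        raise ValueError(f"unknown projection axis {axis!r}")
    return Projection(axis=axis, counts=counts.astype(int))


def evenly_spaced_init(points: np.ndarray, c: int) -> np.ndarray:
    """Deterministic centre initialiser.

    Positions are spread evenly over the occupied index range; the count
    coordinate of each centre starts at the count of the nearest occupied
    point.  Reproducible without any random seed.
    """
    points = np.asarray(points, dtype=float)
    lo, hi = points[:, 0].min(), points[:, 0].max()
    pos = np.linspace(lo, hi, c) if c > 1 else np.array([(lo + hi) / 2.0])
    centers = np.empty((c, 2))
    for k, p in enumerate(pos):
        nearest = int(np.argmin(np.abs(points[:, 0] - p)))
        centers[k] = (p, points[nearest, 1])
    return centers


def _memberships(points: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership update u_ik = 1 / sum_l (d_ik/d_il)^(2/(m-1)).

    A point coincident with a centre gets membership 1 for that centre
    (split evenly if several centres coincide with it).
    """
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    U = np.zeros((points.shape[0], centers.shape[0]))
    singular = d2 <= 0.0
    sing_rows = singular.any(axis=1)
    if sing_rows.any():
        hits = singular[sing_rows]
        U[sing_rows] = hits / hits.sum(axis=1, keepdims=True)
    reg = ~sing_rows
    if reg.any():
        inv = d2[reg] ** (-1.0 / (m - 1.0))
        U[reg] = inv / inv.sum(axis=1, keepdims=True)
    return U


def fcm_cluster(
    points: np.ndarray,
    c: int,
    m: float = 2.0,
    epsilon: float = 1e-5,
    max_iter: int = 200,
    init: np.ndarray | None = None,
) -> AxisClustering:
    """Fuzzy c-means by alternating membership/centre updates.

    Stops when the objective A changes by less than ``epsilon`` between
    consecutive iterations, or after ``max_iter`` iterations.  Deterministic
    for a given ``init`` (defaults to :func:`evenly_spaced_init`).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (position, count) pairs")
    n = points.shape[0]
    if not 1 <= c <= n:
        raise ValueError(f"need n >= c >= 1, got n={n}, c={c}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")

    centers = evenly_spaced_init(points, c) if init is None else np.array(init, dtype=float)
    if centers.shape != (c, 2):
        raise ValueError(f"init must have shape ({c}, 2)")

    trace: list[float] = []
    u_trace: list[np.ndarray] = []
    U = _memberships(points, centers, m)
    u_trace.append(U.copy())
    prev_A = np.inf
    for _ in range(max_iter):
        # centre update: weighted mean with weights u^m
        W = U ** m
        centers = (W.T @ points) / W.sum(axis=0)[:, None]
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        A = float((W * d2).sum())
        trace.append(A)
        if abs(prev_A - A) < epsilon:
            break
        prev_A = A
        U = _memberships(points, centers, m)
        u_trace.append(U.copy())

    return AxisClustering(
        c=c,
        m=m,
        points=points,
        centers=centers,
        U=U,
        objective_trace=np.array(trace),
        labels=np.argmax(U, axis=1),
        membership_trace=tuple(u_trace),
    )


def _middle_cluster(clustering: AxisClustering) -> int:
    """Pick the foreground (middle) cluster.

    With three clusters this is the one whose centre position is the median;
    with two (degenerate support) the one carrying the larger total sensed
    count, tie going to the lower centre position; with one, that cluster.
    """
    order = np.argsort(clustering.centers[:, 0], kind="stable")
    if clustering.c >= 3:
        return int(order[clustering.c // 2])
    if clustering.c == 2:
        totals = clustering.U.T @ clustering.points[:, 1]
        best = np.flatnonzero(totals == totals.max())
        if len(best) > 1:
            best = best[np.argsort(clustering.centers[best, 0], kind="stable")]
        return int(best[0])
    return 0


def find_middle_axis(proj: Projection, cfg: RunConfig) -> tuple[int, AxisClustering]:
    """Middle axis of one projection: max-membership index of the middle cluster.

    Only occupied positioning indexes are clustered.  If fewer occupied
    indexes than the configured cluster count exist, c is reduced to the
    occupied count (down to a single index, which is then the axis).  Ties
    in maximal membership break to the lower index.

    The projection is first brought to a canonical orientation (the
    lexicographically larger of the count vector and its reverse is
    clustered, and the axis mapped back).  Both orientations of the same
    physical map therefore run through one identical computation, so
    mirroring the input mirrors the middle axis exactly, untouched by
    floating-point asymmetries of the clustering trajectory.
    """
    counts = proj.counts
    flipped = tuple(counts[::-1]) > tuple(counts)
    if flipped:
        proj = Projection(axis=proj.axis, counts=counts[::-1].copy())
    points = proj.points()
    if points.shape[0] == 0:
        raise ValueError(f"degenerate {proj.axis} projection: no sensed points")
    c = min(cfg.fcm.n_clusters, points.shape[0])
    clustering = fcm_cluster(
        points, c=c, m=cfg.fcm.m, epsilon=cfg.fcm.epsilon, max_iter=cfg.fcm.max_iter
    )
    mid = _middle_cluster(clustering)
    member = clustering.U[:, mid]
    best = int(np.argmax(member))  # argmax returns the first (lowest) index on ties
    axis = int(points[best, 0])
    return (len(counts) - 1 - axis if flipped else axis), clustering


def find_trunk_middle_point(bm: BinaryMap, cfg: RunConfig) -> MiddleAxes:
    """Trunk middle point from the pressure sensed-point map.

    The horizontal projection yields the trunk line (a column); the
    vertical projection yields the waist (a row); their crossing is the
    middle point used to cut the trunk into four quadrants.
    """
    col, _ = find_middle_axis(project_histogram(bm, "horizontal"), cfg)
    row, _ = find_middle_axis(project_histogram(bm, "vertical"), cfg)
    return MiddleAxes(horizontal_axis=col, vertical_axis=row, cross_point=(row, col))


def find_leg_middle_axis(bm: BinaryMap, cfg: RunConfig) -> tuple[int, AxisClustering]:
    """Middle axis (column) of the leg mass on the thermal sensed-point map."""
    return find_middle_axis(project_histogram(bm, "horizontal"), cfg)
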