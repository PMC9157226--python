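"""Per-frame step vectors, heading angles and traveled distance.

For each pair of consecutive valid frames within a contiguous tracked
segment, the displacement vector v = (vx, vy) defines one step.  Its
heading is the compass angle between v and the up-slope unit vector
w = (0, 1), obtained from the normalized dot product
cos(a) = v.w / |v| = vy / |v| and disambiguated by the sign of vx, so that
0 deg = straight up-slope, 90 deg = across-slope rightward, 180 deg =
straight down, 270 deg = leftward.  Steps shorter than ``min_step`` carry
no heading (tracker jitter has no meaningful direction) but still count
toward traveled distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_tracking import Trajectory

#: steps below this length (cm) carry no heading; they still add to distance.
DEFAULT_MIN_STEP = 0.2


@dataclass(frozen=True)
class StepVector:
    frame_index: int
    vx: float
    vy: float
    length: float
    heading: float  # deg in [0, 360); NaN when not a valid direction
    mid_x: float
    mid_y: float
    is_valid_direction: bool

    @property
    def v(self) -> tuple[float, float]:
        return (self.vx, self.vy)

    @property
    def midpoint(self) -> tuple[float, float]:
        return (self.mid_x, self.mid_y)


@dataclass
class StepVectors:
    """Array-of-columns container for the steps of one trajectory.

    Indexing yields :class:`StepVector` views; the arrays are what the
    zone/direction modules consume.
    """

    frame_index: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    length: np.ndarray
    heading: np.ndarray
    mid_x: np.ndarray
    mid_y: np.ndarray
    is_valid_direction: np.ndarray

    def __len__(self) -> int:
        return len(self.length)

    def __getitem__(self, i: int) -> StepVector:
        return StepVector(
            frame_index=int(self.frame_index[i]),
            vx=float(self.vx[i]),
            vy=float(self.vy[i]),
            length=float(self.length[i]),
            heading=float(self.heading[i]),
            mid_x=float(self.mid_x[i]),
            mid_y=float(self.mid_y[i]),
            is_valid_direction=bool(self.is_valid_direction[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))


def heading_from_vector(v: tuple[float, float]) -> float:
    """Compass heading (deg in [0, 360)) of a displacement vector.

    Computed from the dot product with the up-slope unit vector (0, 1):
    a0 = arccos(vy/|v|) in [0, 180], mirrored into the left hemisphere
    (360 - a0) when vx < 0.  The zero vector has no heading.
    """
    vx, vy = float(v[0]), float(v[1])
    norm = np.hypot(vx, vy)
    if norm == 0.0:
        raise ValidationError("zero vector has no heading")
    a0 = float(np.degrees(np.arccos(np.clip(vy / norm, -1.0, 1.0))))
    return a0 % 360.0 if vx >= 0 else (360.0 - a0) % 360.0


def _headings(vx: np.ndarray, vy: np.ndarray, length: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        a0 = np.degrees(np.arccos(np.clip(vy / length, -1.0, 1.0)))
    h = np.where(vx >= 0, a0, 360.0 - a0) % 360.0
    h[length == 0] = np.nan
    return h


def step_vectors(traj: Trajectory, min_step: float = DEFAULT_MIN_STEP) -> StepVectors:
    """All steps between consecutive valid frames, segment by segment."""
    if min_step < 0:
        raise ValueError("min_step must be >= 0")
    if np.count_nonzero(traj.valid) < 2:
        raise ValidationError("need at least 2 valid frames")
    idx, vx, vy, mx, my = [], [], [], [], []
    for start, stop in traj.segments():
        if stop - start < 2:
            continue
        x = traj.x[start:stop]
        y = traj.y[start:stop]
        idx.append(np.arange(start, stop - 1))
        vx.append(np.diff(x))
        vy.append(np.diff(y))
        mx.append((x[:-1] + x[1:]) / 2.0)
        my.append((y[:-1] + y[1:]) / 2.0)
    if not idx:
        raise ValidationError("no contiguous segment with 2+ valid frames")
    frame_index = np.concatenate(idx)
    vx = np.concatenate(vx)
    vy = np.concatenate(vy)
    length = np.hypot(vx, vy)
    heading = _headings(vx, vy, length)
    directed = length >= max(min_step, np.finfo(float).tiny)
    heading = np.where(directed, heading, np.nan)
    return StepVectors(
        frame_index=frame_index,
        vx=vx,
        vy=vy,
        length=length,
        heading=heading,
        mid_x=np.concatenate(mx),
        mid_y=np.concatenate(my),
        is_valid_direction=directed,
    )


def total_distance(traj: Trajectory) -> float:
    """Cumulative traveled distance over all steps, in meters.

    Sub-``min_step`` steps are included: distance is a pure path-length
    integral, independent of the direction-scoring threshold.
    """
    steps = step_vectors(traj, min_step=0.0)
    return float(steps.length.sum()) / 100.0


def smooth_trajectory(traj: Trajectory, window: int) -> Trajectory:
    """Centered moving-average position smoothing within valid segments.

    ``window`` must be odd; endpoints of each segment use a shrunken
    symmetric window.  Optional preprocessing; off by default everywhere.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    out = traj.copy()
    half = window // 2
    for start, stop in traj.segments():
        for arr, src in ((out.x, traj.x), (out.y, traj.y)):
            seg = src[start:stop]
            sm = np.empty_like(seg)
            for k in range(len(seg)):
                lo = max(0, k - half)
                hi = min(len(seg), k + half + 1)
                r = min(k - lo, hi - 1 - k)
                sm[k] = seg[k - r : k + r + 1].mean()
            arr[start:stop] = sm
    return out
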