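"""Wall-zone geometry, bottom-strip occupancy and coast-to-coast traversals.

An animal within ``wall_zone`` cm of a wall counts as "at" that wall.  A
coast-to-coast traversal is a continuous passage from one wall zone to the
opposite one; each travel axis (left-right, bottom-top) is scored
independently, so an animal hugging the bottom edge while crossing
left-to-right produces exactly one horizontal event — its permanent
residence in the bottom wall zone does not interrupt it.

Events are classified by where and how straight they run:

* ``bottom_horizontal`` — horizontal event whose mean y lies in the bottom
  strip (travel along the lower edge);
* ``upper_horizontal`` — horizontal event above the strip with mean
  perpendicular drift at most ``drift_max``;
* ``vertical`` — vertical event with drift at most ``drift_max``;
* ``diagonal`` — either axis, drifting more than ``drift_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_tracking import Trajectory
from .kinematics import step_vectors

#: classification bound (cm) on mean perpendicular drift of an event.
DEFAULT_DRIFT_MAX = 15.0


@dataclass
class ZoneMembership:
    """Per-frame booleans for the four wall zones and the bottom strip."""

    in_left: np.ndarray
    in_right: np.ndarray
    in_bottom: np.ndarray
    in_top: np.ndarray
    in_strip: np.ndarray


@dataclass(frozen=True)
class TraversalEvent:
    axis: str  # 'horizontal' | 'vertical'
    category: str  # 'bottom_horizontal' | 'upper_horizontal' | 'vertical' | 'diagonal'
    start_frame: int
    end_frame: int
    path_length: float  # cm
    perp_drift: float  # cm
    mean_y: float  # cm


@dataclass(frozen=True)
class StripOccupancy:
    """Distance traveled in the bottom strip vs the area-based expectation.

    ``expected`` is the strip's share of arena height times the total
    distance — the distance a spatially indifferent animal would lay down
    in the strip.
    """

    observed: float  # m
    total: float  # m
    expected: float  # m
    strip_fraction: float


def zone_membership(traj: Trajectory) -> ZoneMembership:
    a = traj.arena
    x, y, v = traj.x, traj.y, traj.valid
    return ZoneMembership(
        in_left=v & (x <= a.wall_zone),
        in_right=v & (x >= a.width - a.wall_zone),
        in_bottom=v & (y <= a.wall_zone),
        in_top=v & (y >= a.height - a.wall_zone),
        in_strip=v & (y <= a.strip),
    )


def _visits(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Compress a per-frame -1/0/+1 zone-label sequence into visits.

    Returns ``(zone, first_frame, last_frame)`` for each maximal run of a
    nonzero label (zero frames separate visits but carry no zone).
    """
    visits = []
    n = len(labels)
    i = 0
    while i < n:
        z = labels[i]
        if z == 0:
            i += 1
            continue
        j = i
        while j < n and labels[j] == z:
            j += 1
        visits.append((int(z), i, j - 1))
        i = j
    return visits


def detect_traversals(
    traj: Trajectory, drift_max: float = DEFAULT_DRIFT_MAX
) -> list[TraversalEvent]:
    """Coast-to-coast events on both axes, classified by strip and drift.

    A traversal spans from the last frame of a wall-zone visit to the first
    frame of the next visit to the *opposite* zone on the same axis.
    ``path_length`` integrates step lengths over the spanned frames;
    ``perp_drift`` is the mean absolute deviation of the cross-axis
    coordinate from its value at the start frame.
    """
    zm = zone_membership(traj)
    steps = step_vectors(traj, min_step=0.0)
    events: list[TraversalEvent] = []
    for axis, neg, pos, perp in (
        ("horizontal", zm.in_left, zm.in_right, traj.y),
        ("vertical", zm.in_bottom, zm.in_top, traj.x),
    ):
        labels = np.zeros(traj.n_frames, dtype=int)
        labels[neg] = -1
        labels[pos] = 1
        visits = _visits(labels)
        for (z0, _, last0), (z1, first1, _) in zip(visits, visits[1:]):
            if z0 == z1:
                continue
            start, end = last0, first1
            frames = slice(start, end + 1)
            fv = traj.valid[frames]
            mean_y = float(np.mean(traj.y[frames][fv]))
            drift = float(
                np.mean(np.abs(perp[frames][fv] - perp[start]))
            )
            in_span = (steps.frame_index >= start) & (steps.frame_index + 1 <= end)
            plen = float(steps.length[in_span].sum())
            if axis == "horizontal":
                if mean_y <= traj.arena.strip:
                    cat = "bottom_horizontal"
                elif drift <= drift_max:
                    cat = "upper_horizontal"
                else:
                    cat = "diagonal"
            else:
                cat = "vertical" if drift <= drift_max else "diagonal"
            events.append(
                TraversalEvent(
                    axis=axis,
                    category=cat,
                    start_frame=start,
                    end_frame=end,
                    path_length=plen,
                    perp_drift=drift,
                    mean_y=mean_y,
                )
            )
    return events


def strip_occupancy(traj: Trajectory) -> StripOccupancy:
    """Observed vs expected distance traveled in the bottom strip (meters).

    Steps are assigned to the strip by their midpoint; the error of that
    assignment is bounded by one step length.
    """
    steps = step_vectors(traj, min_step=0.0)
    total = float(steps.length.sum()) / 100.0
    observed = float(steps.length[steps.mid_y <= traj.arena.strip].sum()) / 100.0
    frac = traj.arena.strip_fraction
    return StripOccupancy(
        observed=observed,
        total=total,
        expected=frac * total,
        strip_fraction=frac,
    )
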