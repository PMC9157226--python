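"""Head-roll measurement from eye keypoints (frontal-view frames).

The lateral head axis is the line connecting the two eyes (or ear bases;
the operation is landmark-agnostic).  Head roll is the acute angle between
that line and the image horizontal, in [0, 90] degrees: 0 means a level
head, 90 a head rotated fully sideways.  The statistic is unsigned — the
magnitude of roll is what indexes head leveling; the signed angle is
available via ``signed=True`` for anyone who needs roll direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: minimum accepted frames per animal (the sparsest animals in frontal-view
#: capture still yield about this many usable frames)
DEFAULT_MIN_FRAMES = 9


@dataclass(frozen=True)
class EyeFrame:
    frame_id: int
    left_eye: tuple[float, float]
    right_eye: tuple[float, float]
    units: str = "px"  # 'px' | 'cm'; roll is scale-invariant either way


@dataclass
class HeadAngleSummary:
    angles: np.ndarray  # per-frame roll, deg in [0, 90]
    mean: float
    n_frames: int


def head_roll(f: EyeFrame, signed: bool = False) -> float:
    """Roll angle of the inter-eye line relative to the image horizontal.

    Unsigned by default (acute angle in [0, 90]); invariant to swapping
    the left/right labels and to uniform scaling of the coordinates.
    """
    dx = f.right_eye[0] - f.left_eye[0]
    dy = f.right_eye[1] - f.left_eye[1]
    if dx == 0.0 and dy == 0.0:
        raise ValidationError("coincident eye points define no head axis")
    a = float(np.degrees(np.arctan2(dy, dx)))
    # fold to the acute angle with the horizontal axis
    mag = abs(a)
    if mag > 90.0:
        mag = 180.0 - mag
        a = a - 180.0 if a > 0 else a + 180.0
    return a if signed else mag


def summarize_head_angle(
    frames: Sequence[EyeFrame], min_frames: int = DEFAULT_MIN_FRAMES
) -> HeadAngleSummary:
    """Arithmetic mean of per-frame roll angles for one animal."""
    if len(frames) < min_frames:
        raise ValidationError(
            f"need at least {min_frames} frames, got {len(frames)}"
        )
    angles = np.array([head_roll(f) for f in frames])
    return HeadAngleSummary(angles=angles, mean=float(angles.mean()), n_frames=len(angles))


def read_eye_frames(path: str | Path, units: str = "px") -> list[EyeFrame]:
    """Read a keypoint CSV with columns frame_id, lx, ly, rx, ry."""
    df = pd.read_csv(path)
    required = ["frame_id", "lx", "ly", "rx", "ry"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        EyeFrame(
            frame_id=int(r.frame_id),
            left_eye=(float(r.lx), float(r.ly)),
            right_eye=(float(r.rx), float(r.ry)),
            units=units,
        )
        for r in df.itertuples()
    ]


def write_eye_frames(frames: Sequence[EyeFrame], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "frame_id": [f.frame_id for f in frames],
            "lx": [f.left_eye[0] for f in frames],
            "ly": [f.left_eye[1] for f in frames],
            "rx": [f.right_eye[0] for f in frames],
            "ry": [f.right_eye[1] for f in frames],
        }
    ).to_csv(path, index=False)
    return path
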