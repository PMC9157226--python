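"""Reading, writing and validation of open-field tracking time series.

The arena is a square tilted floor viewed from a camera mounted
perpendicular to it, so all coordinates live in the floor plane: the origin
is the lower-left corner of the tilted floor, ``x`` runs across-slope
(rightward) and ``y`` runs up-slope.  Two CSV dialects are supported:

``canonical``
    ``# key=value`` metadata lines followed by a ``t,x,y,valid`` table.
    Lossless: :func:`write_tracking` then :func:`read_tracking` is the
    identity.

``raw_export``
    The tracker-export style: a ``Key: value`` header block terminated by a
    column-header row containing ``Trial time``, ``X center`` and
    ``Y center`` columns, comma separated, with ``-`` as the missing-value
    token.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import ParseError, ValidationError

SPECIES = ("rat", "sand_rat", "jird", "synthetic")

#: positions up to this many cm outside the arena are treated as tracker
#: jitter and clamped onto the boundary; anything further out is an error.
CLAMP_TOL_CM = 1.0

#: default maximum dropout run (frames) that interpolation will bridge,
#: about 0.5 s at 25 fps.  Longer gaps split the analysis into segments.
DEFAULT_MAX_GAP = 12


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and sampling of one inclined open-field session.

    All lengths in cm, the inclination in degrees from horizontal, and the
    frame rate in frames per second.  ``wall_zone`` is the band next to each
    wall within which the animal is scored "at the wall"; ``strip`` is the
    band along the lower (downhill) edge used for the bottom-strip analyses.
    """

    width: float = 100.0
    height: float = 100.0
    inclination: float = 0.0
    wall_zone: float = 20.0
    strip: float = 15.0
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValidationError("arena width and height must be positive")
        if not (0.0 <= self.inclination <= 90.0):
            raise ValidationError(
                f"inclination must lie in [0, 90], got {self.inclination}"
            )
        if not (0.0 < self.wall_zone < min(self.width, self.height) / 2):
            raise ValidationError(
                f"wall_zone must lie in (0, {min(self.width, self.height) / 2}), "
                f"got {self.wall_zone}"
            )
        if not (0.0 < self.strip < self.height):
            raise ValidationError(
                f"strip must lie in (0, {self.height}), got {self.strip}"
            )
        if not self.frame_rate > 0:
            raise ValidationError("frame_rate must be positive")

    @property
    def strip_fraction(self) -> float:
        """Fraction of the arena height covered by the bottom strip."""
        return self.strip / self.height


@dataclass
class Trajectory:
    """One subject's tracked positions over one session.

    ``t`` is strictly increasing time in seconds; ``x``/``y`` are positions
    in cm in the floor plane; ``valid`` flags frames where the tracker
    produced a position.  Positions on invalid frames are undefined
    (stored as NaN).
    """

    subject_id: str
    species: str
    arena: ArenaSpec
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.species not in SPECIES:
            raise ValidationError(
                f"unknown species {self.species!r}; expected one of {SPECIES}"
            )
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValidationError("t, x, y, valid must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("time must be strictly increasing")
        self._clamp_positions()

    def _clamp_positions(self) -> None:
        a = self.arena
        for arr, hi, name in ((self.x, a.width, "x"), (self.y, a.height, "y")):
            v = arr[self.valid]
            if v.size == 0:
                continue
            if np.any(np.isnan(v)):
                raise ValidationError(f"NaN {name} position on a valid frame")
            if np.any(v < -CLAMP_TOL_CM) or np.any(v > hi + CLAMP_TOL_CM):
                bad = float(v[(v < -CLAMP_TOL_CM) | (v > hi + CLAMP_TOL_CM)][0])
                raise ValidationError(
                    f"{name} position {bad:.2f} cm lies more than "
                    f"{CLAMP_TOL_CM} cm outside the arena"
                )
            arr[self.valid] = np.clip(v, 0.0, hi)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def segments(self) -> Iterator[tuple[int, int]]:
        """Yield ``(start, stop)`` half-open index ranges of contiguous
        valid frames."""
        v = self.valid
        n = len(v)
        i = 0
        while i < n:
            if v[i]:
                j = i
                while j < n and v[j]:
                    j += 1
                yield i, j
                i = j
            else:
                i += 1

    def copy(self) -> "Trajectory":
        return Trajectory(
            subject_id=self.subject_id,
            species=self.species,
            arena=self.arena,
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            valid=self.valid.copy(),
        )


_ARENA_FIELDS = ("width", "height", "inclination", "wall_zone", "strip", "frame_rate")


def _check_coverage(valid: np.ndarray) -> None:
    if valid.size and np.count_nonzero(~valid) > 0.5 * valid.size:
        raise ValidationError(
            f"more than 50% of frames are missing "
            f"({np.count_nonzero(~valid)}/{valid.size})"
        )


def read_tracking(path: str | Path, dialect: str = "canonical") -> Trajectory:
    """Read a tracking CSV in either dialect into a validated Trajectory."""
    path = Path(path)
    if dialect == "canonical":
        return _read_canonical(path)
    if dialect == "raw_export":
        return _read_raw_export(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_canonical(path: Path) -> Trajectory:
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float, bool]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ParseError(f"{path}:{lineno}: malformed metadata line {line!r}")
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols != ["t", "x", "y", "valid"]:
                    raise ParseError(
                        f"{path}:{lineno}: expected header t,x,y,valid, got {line!r}"
                    )
                header_seen = True
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {line!r}")
            ok = parts[3] in ("1", "true", "True")
            try:
                t = float(parts[0])
                x = float(parts[1]) if parts[1] else math.nan
                y = float(parts[2]) if parts[2] else math.nan
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            rows.append((t, x, y, ok))
    if not header_seen:
        raise ParseError(f"{path}: missing t,x,y,valid header")
    arena = ArenaSpec(**{f: float(meta[f]) for f in _ARENA_FIELDS if f in meta})
    t = np.array([r[0] for r in rows])
    x = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    valid = np.array([r[3] for r in rows], dtype=bool)
    _check_coverage(valid)
    return Trajectory(
        subject_id=meta.get("subject_id", path.stem),
        species=meta.get("species", "synthetic"),
        arena=arena,
        t=t,
        x=x,
        y=y,
        valid=valid,
    )


_RAW_REQUIRED = ("Trial time", "X center", "Y center")
_RAW_MISSING = "-"


def _read_raw_export(path: Path) -> Trajectory:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = None
    col_idx: dict[str, int] = {}
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        cols = [c.strip() for c in stripped.split(",")]
        if _RAW_REQUIRED[0] in cols:
            missing = [c for c in _RAW_REQUIRED if c not in cols]
            if missing:
                raise ParseError(
                    f"{path}:{lineno}: column header missing {missing}"
                )
            col_idx = {c: cols.index(c) for c in _RAW_REQUIRED}
            data_start = lineno  # 1-based; data begins on the next line
            break
        if ":" not in stripped:
            raise ParseError(
                f"{path}:{lineno}: malformed header line {stripped!r} "
                "(expected 'Key: value')"
            )
        k, v = stripped.split(":", 1)
        meta[k.strip().lower()] = v.strip()
    if data_start is None:
        raise ParseError(f"{path}: no column-header row containing 'Trial time'")

    ts, xs, ys, valids = [], [], [], []
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        stripped = line.strip()
        if not stripped:
            continue
        parts = [p.strip() for p in stripped.split(",")]
        try:
            t = float(parts[col_idx["Trial time"]])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{lineno}: unreadable time field") from None
        px, py = parts[col_idx["X center"]], parts[col_idx["Y center"]]
        if px == _RAW_MISSING or py == _RAW_MISSING:
            ts.append(t)
            xs.append(math.nan)
            ys.append(math.nan)
            valids.append(False)
            continue
        try:
            xs.append(float(px))
            ys.append(float(py))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: unreadable coordinate field") from None
        ts.append(t)
        valids.append(True)

    arena_kwargs = {}
    if "inclination" in meta:
        arena_kwargs["inclination"] = float(meta["inclination"])
    if "frame rate" in meta:
        arena_kwargs["frame_rate"] = float(meta["frame rate"])
    valid = np.array(valids, dtype=bool)
    _check_coverage(valid)
    return Trajectory(
        subject_id=meta.get("subject", path.stem),
        species=meta.get("species", "synthetic"),
        arena=ArenaSpec(**arena_kwargs),
        t=np.array(ts),
        x=np.array(xs),
        y=np.array(ys),
        valid=valid,
    )


def write_tracking(traj: Trajectory, path: str | Path) -> Path:
    """Write a Trajectory as a canonical-dialect CSV (lossless round trip)."""
    path = Path(path)
    bad = traj.valid & (np.isnan(traj.x) | np.isnan(traj.y))
    if np.any(bad):
        raise ValidationError("NaN position on a valid frame; cannot serialize")
    with open(path, "w") as fh:
        fh.write(f"# subject_id={traj.subject_id}\n")
        fh.write(f"# species={traj.species}\n")
        for f in _ARENA_FIELDS:
            fh.write(f"# {f}={getattr(traj.arena, f)!r}\n")
        fh.write("t,x,y,valid\n")
        for t, x, y, ok in zip(traj.t, traj.x, traj.y, traj.valid):
            if ok:
                fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r},1\n")
            else:
                fh.write(f"{float(t)!r},,,0\n")
    return path


def interpolate_gaps(traj: Trajectory, max_gap: int = DEFAULT_MAX_GAP) -> Trajectory:
    """Fill dropout runs of at most ``max_gap`` frames by linear interpolation.

    Only runs flanked by valid frames on both sides are filled (no
    extrapolation at the session edges); longer runs are left invalid and
    split downstream analyses into independent segments.  Valid frames are
    never altered.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = traj.copy()
    v = out.valid
    n = len(v)
    i = 0
    while i < n:
        if not v[i]:
            j = i
            while j < n and not v[j]:
                j += 1
            run = j - i
            if 0 < i and j < n and run <= max_gap:
                t0, t1 = out.t[i - 1], out.t[j]
                for k in range(i, j):
                    w = (out.t[k] - t0) / (t1 - t0)
                    out.x[k] = out.x[i - 1] * (1 - w) + out.x[j] * w
                    out.y[k] = out.y[i - 1] * (1 - w) + out.y[j] * w
                    v[k] = True
            i = j
        else:
            i += 1
    return out
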