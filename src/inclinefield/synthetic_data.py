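"""Synthetic trajectories and eye keypoints with known ground truth.

The generator emulates the statistical structure of rodent exploration on
an inclined open-field: a two-state behavioral Markov chain alternates an
*edge-follow* state (thigmotactic travel along the bottom strip) with an
*explore* state, in which per-frame headings are drawn from a von Mises
mixture centered on the four cardinal directions (up-slope, down-slope,
left, right) plus a uniform component, blended with the previous heading
through a persistence weight (a correlated random walk).  Step lengths are
Gamma distributed; walls reflect.  Every draw comes from one seeded
generator, so an identical seed reproduces the trajectory bit for bit.

``make_cohort`` builds whole experiment-shaped cohorts — several
inclination levels, n subjects per level — with per-level parameter
profiles; the shipped ``empirical_trend_profile`` makes activity decline and
edge-following plus vertical travel rise with inclination, the trends the
analysis layer is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .head_posture import EyeFrame
from .io_tracking import ArenaSpec, Trajectory


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated session.

    ``heading_weights`` are (w_up, w_down, w_left, w_right, w_uniform) for
    the explore-state heading mixture; ``p_edge`` is the stationary
    probability of the edge-follow state and ``state_dwell`` its mean dwell
    time in frames; ``persistence`` in [0, 1) is the weight of the previous
    heading in the circular blend.  Step lengths are Gamma with mean
    ``step_mean`` cm/frame and coefficient of variation ``step_cv``.
    """

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    duration: float = 1800.0  # s; a full 30-min session
    seed: int = 0
    step_mean: float = 0.2  # cm per frame (~90 m per 30-min session)
    step_cv: float = 0.6
    persistence: float = 0.75
    p_edge: float = 0.2
    heading_weights: tuple[float, float, float, float, float] = (
        0.15,
        0.15,
        0.15,
        0.15,
        0.4,
    )
    kappa: float = 12.0
    state_dwell: float = 100.0  # frames (~4 s at 25 fps)

    def __post_init__(self) -> None:
        w = np.asarray(self.heading_weights, dtype=float)
        if len(w) != 5 or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError("heading_weights must be 5 nonnegatives summing to 1")
        if not (self.step_mean > 0 and self.step_cv > 0):
            raise ValidationError("step_mean and step_cv must be positive")
        if not (0.0 <= self.persistence < 1.0):
            raise ValidationError("persistence must lie in [0, 1)")
        if not (0.0 <= self.p_edge <= 1.0):
            raise ValidationError("p_edge must lie in [0, 1]")
        if not (self.duration > 0 and self.state_dwell >= 1 and self.kappa > 0):
            raise ValidationError("duration, state_dwell, kappa out of range")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.arena.frame_rate))


@dataclass
class GroundTruth:
    """Realized state of one simulation run, next to its config."""

    config: SimulationConfig
    n_frames: int
    frames_edge: int
    frames_explore: int
    realized_strip_fraction: float  # fraction of frames with y <= strip


# mixture component centers as compass angles (0 = up-slope)
_CENTERS = np.array([0.0, math.pi, 1.5 * math.pi, 0.5 * math.pi])  # up,down,left,right


def simulate_trajectory(
    cfg: SimulationConfig, subject_id: str = "sim", species: str = "synthetic"
) -> tuple[Trajectory, GroundTruth]:
    """Generate one session frame by frame; deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    a = cfg.arena
    n = cfg.n_frames
    if n < 2:
        raise ValidationError("duration too short for the frame rate")

    # state chain transition probabilities from stationarity + mean dwell
    leave_edge = min(1.0, 1.0 / cfg.state_dwell)
    if cfg.p_edge >= 1.0:
        enter_edge, leave_edge = 1.0, 0.0
    elif cfg.p_edge <= 0.0:
        enter_edge = 0.0
    else:
        enter_edge = min(1.0, cfg.p_edge * leave_edge / (1.0 - cfg.p_edge))

    # pre-draw all randomness (vectorized), consumed per frame
    shape = 1.0 / cfg.step_cv**2
    lengths = rng.gamma(shape, cfg.step_mean / shape, size=n)
    comp = rng.choice(5, size=n, p=np.asarray(cfg.heading_weights))
    vm = rng.vonmises(0.0, cfg.kappa, size=n)
    unif = rng.uniform(0.0, 2.0 * math.pi, size=n)
    target = np.where(comp < 4, _CENTERS[np.minimum(comp, 3)] + vm, unif)
    tx = np.sin(target)
    ty = np.cos(target)
    edge_noise = rng.vonmises(0.0, max(cfg.kappa, 8.0), size=n)
    ex_n = np.sin(edge_noise)
    ey_n = np.cos(edge_noise)
    u_state = rng.uniform(0.0, 1.0, size=n)

    x = np.empty(n)
    y = np.empty(n)
    x[0] = a.width / 2.0
    y[0] = a.height / 2.0
    in_edge = u_state[0] < cfg.p_edge
    edge_dir = 1.0 if u_state[0] < 0.5 else -1.0
    hx, hy = 0.0, 1.0  # current heading unit vector, compass (x=sin, y=cos)
    per = cfg.persistence
    strip, W, H = a.strip, a.width, a.height
    frames_edge = 0
    frames_strip = 1 if y[0] <= strip else 0

    for i in range(1, n):
        u = u_state[i]
        if in_edge:
            if u < leave_edge:
                in_edge = False
        else:
            if u < enter_edge:
                in_edge = True
        if in_edge:
            frames_edge += 1
            if y[i - 1] > strip:
                # descend straight toward the strip (with von Mises noise)
                dx, dy = -ex_n[i], -ey_n[i]  # heading = 180 deg + noise
            else:
                # follow the bottom edge; heading = edge_dir * 90 deg + noise
                dx, dy = edge_dir * ey_n[i], -edge_dir * ex_n[i]
            norm = math.hypot(dx, dy)
            hx, hy = dx / norm, dy / norm
        else:
            bx = per * hx + (1.0 - per) * tx[i]
            by = per * hy + (1.0 - per) * ty[i]
            norm = math.hypot(bx, by)
            if norm < 1e-12:
                bx, by, norm = tx[i], ty[i], 1.0
            hx, hy = bx / norm, by / norm
        L = lengths[i]
        nx = x[i - 1] + L * hx
        ny = y[i - 1] + L * hy
        # reflecting walls
        if nx < 0.0:
            nx = -nx
            if in_edge:
                edge_dir = 1.0
        elif nx > W:
            nx = 2.0 * W - nx
            if in_edge:
                edge_dir = -1.0
        if ny < 0.0:
            ny = -ny
        elif ny > H:
            ny = 2.0 * H - ny
        if in_edge and ny > strip and y[i - 1] <= strip:
            ny = strip  # stay constrained to the strip once on it
        x[i] = nx
        y[i] = ny
        if ny <= strip:
            frames_strip += 1

    t = np.arange(n) / a.frame_rate
    traj = Trajectory(
        subject_id=subject_id,
        species=species,
        arena=a,
        t=t,
        x=x,
        y=y,
        valid=np.ones(n, dtype=bool),
    )
    gt = GroundTruth(
        config=cfg,
        n_frames=n,
        frames_edge=frames_edge,
        frames_explore=n - 1 - frames_edge,
        realized_strip_fraction=frames_strip / n,
    )
    return traj, gt


def _vertical_split(w_vertical: float, w_uniform: float) -> tuple[float, ...]:
    """Heading weights with w_up = w_down = w_vertical/2 and the horizontal
    remainder split evenly."""
    w_h = max(0.0, 1.0 - w_vertical - w_uniform) / 2.0
    return (w_vertical / 2.0, w_vertical / 2.0, w_h, w_h, w_uniform)


#: per-inclination parameter deltas emulating the empirical trends:
#: activity falls, edge-following and vertical preference rise with tilt.
STANDARD_INCLINATIONS = (0, 15, 30, 45, 60, 75, 90)

_PROFILE_TABLE = {
    0: dict(step_mean=0.210, p_edge=0.15, w_vertical=0.28, w_uniform=0.40),
    15: dict(step_mean=0.190, p_edge=0.20, w_vertical=0.36, w_uniform=0.34),
    30: dict(step_mean=0.170, p_edge=0.28, w_vertical=0.44, w_uniform=0.28),
    45: dict(step_mean=0.155, p_edge=0.38, w_vertical=0.52, w_uniform=0.22),
    60: dict(step_mean=0.140, p_edge=0.52, w_vertical=0.62, w_uniform=0.16),
    75: dict(step_mean=0.120, p_edge=0.68, w_vertical=0.72, w_uniform=0.10),
    90: dict(step_mean=0.105, p_edge=0.80, w_vertical=0.80, w_uniform=0.06),
}


def empirical_trend_profile(
    inclination: float, base: SimulationConfig | None = None
) -> SimulationConfig:
    """Config for one inclination level with the empirical trend shape."""
    if base is None:
        base = SimulationConfig()
    levels = sorted(_PROFILE_TABLE)
    nearest = min(levels, key=lambda lv: abs(lv - inclination))
    p = _PROFILE_TABLE[nearest]
    return replace(
        base,
        arena=replace(base.arena, inclination=float(inclination)),
        step_mean=p["step_mean"],
        p_edge=p["p_edge"],
        heading_weights=_vertical_split(p["w_vertical"], p["w_uniform"]),
    )


def flat_profile(
    inclination: float, base: SimulationConfig | None = None
) -> SimulationConfig:
    """Null profile: identical dynamics at every inclination."""
    if base is None:
        base = SimulationConfig()
    return replace(base, arena=replace(base.arena, inclination=float(inclination)))


def make_cohort(
    incl_levels: Sequence[float] = STANDARD_INCLINATIONS,
    n_per_cell: int = 10,
    profile: Callable[[float], SimulationConfig] = empirical_trend_profile,
    seed: int = 0,
    species: str = "synthetic",
) -> list[tuple[Trajectory, GroundTruth]]:
    """A reproducible cohort: ``n_per_cell`` subjects per inclination level.

    Per-subject seeds are drawn once from a root generator, so the cohort
    is a pure function of ``seed`` and any subset can be regenerated.
    """
    root = np.random.default_rng(seed)
    out = []
    for level in incl_levels:
        cfg = profile(level)
        for i in range(n_per_cell):
            sub_seed = int(root.integers(0, 2**31 - 1))
            sid = f"{species}-i{int(level):02d}-s{i:02d}"
            out.append(
                simulate_trajectory(
                    replace(cfg, seed=sub_seed), subject_id=sid, species=species
                )
            )
    return out


def simulate_eye_keypoints(
    mu_roll: float,
    sigma_roll: float,
    n_frames: int,
    seed: int = 0,
    eye_distance: float = 30.0,
) -> list[EyeFrame]:
    """Eye keypoint pairs with signed roll ~ Normal(mu, sigma).

    The signed roll is clipped to [-90, 90]; the *measured* roll
    (:func:`~inclinefield.head_posture.head_roll`) is its unsigned acute
    magnitude in [0, 90], so at mu = 0 the measured angles follow a
    half-normal law.  The inter-eye distance is fixed (roll is
    scale-invariant); the left eye anchors at the origin of each frame.
    """
    if sigma_roll < 0:
        raise ValidationError("sigma_roll must be >= 0")
    rng = np.random.default_rng(seed)
    rolls = rng.normal(mu_roll, sigma_roll, size=n_frames) if sigma_roll > 0 else np.full(
        n_frames, float(mu_roll)
    )
    rolls = np.clip(rolls, -90.0, 90.0)
    frames = []
    for i, r in enumerate(rolls):
        rad = math.radians(r)
        frames.append(
            EyeFrame(
                frame_id=i,
                left_eye=(0.0, 0.0),
                right_eye=(eye_distance * math.cos(rad), eye_distance * math.sin(rad)),
            )
        )
    return frames
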