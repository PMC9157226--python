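"""Compass-rose sector histograms of travel direction in the upper field.

Headings are binned into twelve 30-degree sectors centered on the cardinal
directions: sector 0 covers [345, 15) and means straight up-slope, sector 6
straight down, sectors 3 and 9 horizontal.  Intervals are half-open with
the lower edge inclusive.  Because travel inside the bottom strip is
forced to be horizontal by the geometry, the histogram is normally
computed with strip steps excluded, isolating direction choice in the
upper part of the arena.

Left/right mirror sectors (k and 12-k) can be folded together once a
paired test across animals shows no lateral bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import EmptyHistogramError, ValidationError
from .io_tracking import Trajectory
from .kinematics import DEFAULT_MIN_STEP, step_vectors

N_SECTORS = 12
SECTOR_WIDTH = 30.0

#: mirror pairs (k, 12-k) used by folding and the lateral-bias test
MIRROR_PAIRS = tuple((k, N_SECTORS - k) for k in range(1, 6))


@dataclass
class SectorHistogram:
    """Percent of directed steps per 30-degree heading sector."""

    sector_pct: np.ndarray  # shape (12,)
    n_steps: int
    excluded_strip: bool
    denominator: str = "steps"  # 'steps' | 'frames'


@dataclass
class FoldedHistogram:
    """Hemisphere-folded profile: bins at 0,30,...,180 deg from up-slope.

    Interior bins hold the mirrored sector pair combined (summed by
    default; averaged in ``mode='mean'`` for 12-sector plotting parity);
    the straight-up and straight-down bins pass through.
    """

    folded_pct: np.ndarray  # shape (7,)
    mode: str = "sum"


@dataclass
class HemisphereBiasReport:
    """Paired left-vs-right comparison of mirrored sectors across animals."""

    pairs: tuple[tuple[int, int], ...]
    mean_diff: np.ndarray  # left minus right, percentage points
    t: np.ndarray
    p_raw: np.ndarray
    p_holm: np.ndarray
    no_bias: bool  # True iff no Holm-corrected p < 0.05


def sector_of(heading: float | np.ndarray) -> int | np.ndarray:
    """Sector index of a heading in degrees (vectorized)."""
    k = np.floor((np.asarray(heading) + SECTOR_WIDTH / 2) / SECTOR_WIDTH).astype(int)
    k = k % N_SECTORS
    return int(k) if np.isscalar(heading) else k


def sector_histogram_from_headings(
    headings_deg: Sequence[float],
    excluded_strip: bool = True,
) -> SectorHistogram:
    """Histogram a plain heading sample (used by simulations and tests)."""
    h = np.asarray(headings_deg, dtype=float) % 360.0
    if h.size == 0:
        raise EmptyHistogramError("no headings to bin")
    counts = np.bincount(sector_of(h), minlength=N_SECTORS).astype(float)
    return SectorHistogram(
        sector_pct=100.0 * counts / h.size,
        n_steps=int(h.size),
        excluded_strip=excluded_strip,
    )


def sector_histogram(
    traj: Trajectory,
    exclude_strip: bool = True,
    min_step: float = DEFAULT_MIN_STEP,
    denominator: str = "steps",
) -> SectorHistogram:
    """Sector histogram of one subject's directed steps.

    With ``exclude_strip`` (the default) steps whose midpoint lies in the
    bottom strip are dropped first.  ``denominator='steps'`` expresses
    percentages of the retained directed steps (sums to 100);
    ``denominator='frames'`` uses the session's total frame count instead,
    for parity with per-frame reporting.
    """
    if denominator not in ("steps", "frames"):
        raise ValueError("denominator must be 'steps' or 'frames'")
    steps = step_vectors(traj, min_step=min_step)
    keep = steps.is_valid_direction
    if exclude_strip:
        keep = keep & (steps.mid_y > traj.arena.strip)
    h = steps.heading[keep]
    if h.size == 0:
        raise EmptyHistogramError(
            "no directed steps retained (trajectory confined to the strip "
            "or below the step threshold)"
        )
    counts = np.bincount(sector_of(h), minlength=N_SECTORS).astype(float)
    denom = float(h.size) if denominator == "steps" else float(traj.n_frames)
    return SectorHistogram(
        sector_pct=100.0 * counts / denom,
        n_steps=int(h.size),
        excluded_strip=exclude_strip,
        denominator=denominator,
    )


def fold_hemispheres(h: SectorHistogram, mode: str = "sum") -> FoldedHistogram:
    """Combine mirrored left/right sectors into 7 bins from up to down."""
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    p = h.sector_pct
    out = np.empty(7)
    out[0] = p[0]
    out[6] = p[6]
    for b in range(1, 6):
        pair = p[b] + p[N_SECTORS - b]
        out[b] = pair if mode == "sum" else pair / 2.0
    return FoldedHistogram(folded_pct=out, mode=mode)


def vertical_fraction(h: SectorHistogram) -> float:
    """Percent of directed travel that is strictly up or down (sectors 0+6)."""
    return float(h.sector_pct[0] + h.sector_pct[6])


def hemisphere_bias_test(
    histograms: Sequence[SectorHistogram], alpha: float = 0.05
) -> HemisphereBiasReport:
    """Paired two-sided test of each mirrored sector pair across animals.

    For each pair (k, 12-k) the per-animal difference in sector percentage
    is tested with a paired t test; Holm's step-down correction is applied
    across the five pairs.  ``no_bias`` holds iff no corrected p falls
    below ``alpha`` — the precondition for hemisphere folding.
    """
    if len(histograms) < 3:
        raise ValidationError("hemisphere bias test needs at least 3 animals")
    mat = np.vstack([h.sector_pct for h in histograms])
    tvals, pvals, diffs = [], [], []
    for k, m in MIRROR_PAIRS:
        d = mat[:, k] - mat[:, m]
        diffs.append(float(d.mean()))
        if d.std(ddof=1) == 0.0:
            # degenerate: identical asymmetry in every animal
            t, p = (0.0, 1.0) if d[0] == 0.0 else (np.inf, 0.0)
            tvals.append(t)
            pvals.append(p)
            continue
        t, p = sps.ttest_rel(mat[:, k], mat[:, m])
        tvals.append(float(t))
        pvals.append(float(p))
    p_holm = holm_correction(np.array(pvals))
    return HemisphereBiasReport(
        pairs=MIRROR_PAIRS,
        mean_diff=np.array(diffs),
        t=np.array(tvals),
        p_raw=np.array(pvals),
        p_holm=p_holm,
        no_bias=bool(np.all(p_holm >= alpha)),
    )


def holm_correction(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj
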