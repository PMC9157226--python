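"""End-to-end orchestration of the two experiments.

``run_experiment1`` turns a cohort of tracking sessions (real or
simulated) into (a) a per-animal metric table — total distance, strip
occupancy, traversal counts, sector histograms — (b) group summary tables
(mean +/- SEM distance per species x inclination, expected vs observed
strip distance, traversal-count means, mean sector profiles), and (c) the
statistics bundle: the factorial ANOVA on distance, the per-species
expected/observed repeated-measures ANOVA, the split-plot sector ANOVA,
and Tukey follow-ups of inclination within species.  ``run_experiment2``
does the same for head-roll keypoint sessions with a one-way ANOVA and
Tukey HSD.  Everything is a pure function of the inputs; identical inputs
give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import direction_profile as dp
from . import head_posture as hp
from . import kinematics, stats, zones_events
from .errors import DesignError, EmptyHistogramError, InclineFieldError
from .io_tracking import ArenaSpec, DEFAULT_MAX_GAP, Trajectory, interpolate_gaps, read_tracking

log = logging.getLogger("inclinefield")

EVENT_CATEGORIES = ("bottom_horizontal", "upper_horizontal", "vertical", "diagonal")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``manifest`` maps subjects to input files (columns subject_id, species,
    inclination, file) — or pass loaded trajectories directly to the run
    functions.  ``strict`` turns subject validation failures into errors
    instead of log-and-exclude.
    """

    manifest: pd.DataFrame | None = None
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    out_dir: Path | None = None
    exclude_strip: bool = True
    min_step: float = kinematics.DEFAULT_MIN_STEP
    drift_max: float = zones_events.DEFAULT_DRIFT_MAX
    denominator: str = "steps"
    max_gap: int = DEFAULT_MAX_GAP
    dialect: str = "canonical"
    strict: bool = False


@dataclass
class ReportBundle:
    per_animal: pd.DataFrame
    group_tables: dict[str, pd.DataFrame]
    anovas: dict[str, stats.AnovaResult]
    tukey: dict[str, stats.TukeyResult]
    excluded: list[tuple[str, str]]  # (subject_id, reason)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_animal.to_csv(out_dir / "per_animal.csv", index=False)
        for name, tbl in self.group_tables.items():
            tbl.to_csv(out_dir / f"{name}.csv", index=False)
        report = {
            name: res.to_frame().to_dict(orient="records")
            for name, res in self.anovas.items()
        }
        report["excluded_subjects"] = [
            {"subject_id": s, "reason": r} for s, r in self.excluded
        ]
        with open(out_dir / "anova_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        for name, tk in self.tukey.items():
            tk.table.to_csv(out_dir / f"tukey_{name}.csv", index=False)
        return out_dir


def _load_manifest(cfg: RunConfig) -> list[Trajectory]:
    if cfg.manifest is None:
        raise InclineFieldError("RunConfig.manifest is not set")
    trajs = []
    for row in cfg.manifest.itertuples():
        traj = read_tracking(row.file, dialect=cfg.dialect)
        traj.subject_id = str(row.subject_id)
        traj.species = str(row.species)
        trajs.append((traj, float(row.inclination)))
    return trajs


def animal_metrics(
    traj: Trajectory,
    inclination: float | None = None,
    exclude_strip: bool = True,
    min_step: float = kinematics.DEFAULT_MIN_STEP,
    drift_max: float = zones_events.DEFAULT_DRIFT_MAX,
    denominator: str = "steps",
) -> dict:
    """All per-animal Experiment-1 metrics as one flat record."""
    occ = zones_events.strip_occupancy(traj)
    events = zones_events.detect_traversals(traj, drift_max=drift_max)
    rec = {
        "subject_id": traj.subject_id,
        "species": traj.species,
        "inclination": (
            float(inclination) if inclination is not None else traj.arena.inclination
        ),
        "distance_m": kinematics.total_distance(traj),
        "strip_observed_m": occ.observed,
        "strip_expected_m": occ.expected,
        "strip_total_m": occ.total,
        "strip_share": occ.observed / occ.total if occ.total > 0 else np.nan,
    }
    for cat in EVENT_CATEGORIES:
        rec[f"n_{cat}"] = sum(1 for e in events if e.category == cat)
    try:
        hist = dp.sector_histogram(
            traj,
            exclude_strip=exclude_strip,
            min_step=min_step,
            denominator=denominator,
        )
        for k in range(dp.N_SECTORS):
            rec[f"sector_{k:02d}_pct"] = float(hist.sector_pct[k])
        rec["n_directed_steps"] = hist.n_steps
        rec["vertical_fraction_pct"] = dp.vertical_fraction(hist)
    except EmptyHistogramError:
        for k in range(dp.N_SECTORS):
            rec[f"sector_{k:02d}_pct"] = np.nan
        rec["n_directed_steps"] = 0
        rec["vertical_fraction_pct"] = np.nan
    return rec


def _mean_sem(g: pd.Series) -> str:
    return f"{g.mean():.1f} ± {g.sem():.1f}"


def run_experiment1(
    cfg: RunConfig, trajectories: Sequence[tuple[Trajectory, float]] | None = None
) -> ReportBundle:
    """Full Experiment-1 analysis over a cohort.

    ``trajectories`` is a sequence of (trajectory, inclination) pairs; when
    omitted they are loaded from ``cfg.manifest``.  Subjects that fail
    validation are excluded and logged (or raise, with ``cfg.strict``).
    """
    if trajectories is None:
        trajectories = _load_manifest(cfg)
    records, excluded = [], []
    for traj, incl in trajectories:
        try:
            traj = interpolate_gaps(traj, max_gap=cfg.max_gap)
            records.append(
                animal_metrics(
                    traj,
                    inclination=incl,
                    exclude_strip=cfg.exclude_strip,
                    min_step=cfg.min_step,
                    drift_max=cfg.drift_max,
                    denominator=cfg.denominator,
                )
            )
        except InclineFieldError as exc:
            if cfg.strict:
                raise
            log.warning("excluding subject %s: %s", traj.subject_id, exc)
            excluded.append((traj.subject_id, str(exc)))
    per_animal = pd.DataFrame(records)
    if per_animal.empty:
        raise InclineFieldError("no subject passed validation")

    group_tables = {
        "activity_by_inclination": (
            per_animal.groupby(["inclination", "species"])["distance_m"]
            .agg(mean="mean", sem="sem", n="count")
            .reset_index()
            .assign(
                mean_sem=lambda d: d["mean"].round(1).astype(str)
                + " ± "
                + d["sem"].round(1).astype(str)
            )
        ),
        "strip_expected_observed": (
            per_animal.groupby(["species", "inclination"])[
                ["strip_expected_m", "strip_observed_m"]
            ]
            .agg(["mean", "sem"])
            .reset_index()
        ),
        "traversal_counts": (
            per_animal.groupby(["species", "inclination"])[
                [f"n_{c}" for c in EVENT_CATEGORIES]
            ]
            .mean()
            .reset_index()
        ),
        "sector_profile": (
            per_animal.groupby(["species", "inclination"])[
                [f"sector_{k:02d}_pct" for k in range(dp.N_SECTORS)]
            ]
            .mean()
            .reset_index()
        ),
    }

    anovas: dict[str, stats.AnovaResult] = {}
    tukey: dict[str, stats.TukeyResult] = {}

    dist_tbl = per_animal.rename(columns={"distance_m": "response"})
    try:
        anovas["factorial_distance"] = stats.factorial_anova(
            dist_tbl, factors=["species", "inclination"], response="response"
        )
    except DesignError as exc:
        log.warning("factorial ANOVA skipped: %s", exc)

    for sp, sub in per_animal.groupby("species"):
        long = sub.melt(
            id_vars=["subject_id", "inclination"],
            value_vars=["strip_expected_m", "strip_observed_m"],
            var_name="condition",
            value_name="response",
        )
        try:
            anovas[f"expected_observed_{sp}"] = stats.rm_anova_expected_observed(long)
        except DesignError as exc:
            log.warning("expected/observed ANOVA skipped for %s: %s", sp, exc)
        try:
            groups = [g["distance_m"].to_numpy() for _, g in sub.groupby("inclination")]
            labels = [str(lv) for lv in sorted(sub["inclination"].unique())]
            tukey[f"distance_inclination_{sp}"] = stats.tukey_hsd(groups, labels)
        except DesignError as exc:
            log.warning("Tukey skipped for %s: %s", sp, exc)

    sector_long = per_animal.dropna(subset=["sector_00_pct"]).melt(
        id_vars=["subject_id", "species", "inclination"],
        value_vars=[f"sector_{k:02d}_pct" for k in range(dp.N_SECTORS)],
        var_name="sector",
        value_name="response",
    )
    try:
        anovas["sector_mixed"] = stats.rm_anova_mixed(
            sector_long, between=["species", "inclination"], within="sector"
        )
    except DesignError as exc:
        log.warning("sector split-plot ANOVA skipped: %s", exc)

    bundle = ReportBundle(
        per_animal=per_animal,
        group_tables=group_tables,
        anovas=anovas,
        tukey=tukey,
        excluded=excluded,
    )
    if cfg.out_dir is not None:
        bundle.write(cfg.out_dir)
    return bundle


def run_experiment2(
    cfg: RunConfig,
    keypoints: Sequence[tuple[str, str, Sequence[hp.EyeFrame]]] | None = None,
    min_frames: int = hp.DEFAULT_MIN_FRAMES,
) -> ReportBundle:
    """Head-posture analysis: per-animal mean roll, one-way ANOVA, Tukey.

    ``keypoints`` is a sequence of (subject_id, species, frames); when
    omitted, ``cfg.manifest`` rows (subject_id, species, file) point at
    keypoint CSVs.
    """
    if keypoints is None:
        if cfg.manifest is None:
            raise InclineFieldError("RunConfig.manifest is not set")
        keypoints = [
            (str(r.subject_id), str(r.species), hp.read_eye_frames(r.file))
            for r in cfg.manifest.itertuples()
        ]
    records, excluded = [], []
    for sid, sp, frames in keypoints:
        try:
            summ = hp.summarize_head_angle(frames, min_frames=min_frames)
            records.append(
                {
                    "subject_id": sid,
                    "species": sp,
                    "mean_head_angle_deg": summ.mean,
                    "n_frames": summ.n_frames,
                }
            )
        except InclineFieldError as exc:
            if cfg.strict:
                raise
            log.warning("excluding subject %s: %s", sid, exc)
            excluded.append((sid, str(exc)))
    per_animal = pd.DataFrame(records)
    if per_animal.empty:
        raise InclineFieldError("no subject passed validation")

    group_tables = {
        "head_angle_by_species": (
            per_animal.groupby("species")["mean_head_angle_deg"]
            .agg(mean="mean", sem="sem", n="count")
            .reset_index()
        )
    }
    species = sorted(per_animal["species"].unique())
    groups = [
        per_animal.loc[per_animal["species"] == sp, "mean_head_angle_deg"].to_numpy()
        for sp in species
    ]
    anovas, tukey = {}, {}
    try:
        anovas["head_angle_oneway"] = stats.one_way_anova(groups)
        tukey["head_angle_species"] = stats.tukey_hsd(groups, species)
    except DesignError as exc:
        log.warning("Experiment-2 statistics skipped: %s", exc)

    bundle = ReportBundle(
        per_animal=per_animal,
        group_tables=group_tables,
        anovas=anovas,
        tukey=tukey,
        excluded=excluded,
    )
    if cfg.out_dir is not None:
        bundle.write(cfg.out_dir)
    return bundle
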