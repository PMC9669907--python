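"""End-to-end synthetic study: teams x (2 x 2 x 2) design -> measures -> models.

``run_experiment`` simulates every trial of a multi-team session (default
10 teams x 8 condition cells x 2 blocks = 160 trials), generates matched
talk/silence series, computes all per-trial measures (performance, talk
magnitude, catRQA at the operator/ground/team levels, search-area overlap),
and fits the repeated-measures ANOVAs and random-intercept regressions.
Everything is reproducible from ``master_seed``: each trial's seed is derived
from (master_seed, team, cell, block) and is independent of execution order.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import containment_rate, talk_proportion
from .overlap import (
    DegenerateGeometryError,
    preprocess_trajectory,
    proportion_overlap,
    search_polygon,
)
from .policy import PolicyParams, ScriptedPolicy
from .rqa import catrqa_trial
from .sim import ConditionDesign, SimParams, TrialRecord, run_trial
from .speech import SpeakerActivity, SpeechParams, generate_activity
from .stats import mixed_regression, rm_anova_2x2x2

__all__ = [
    "CELLS",
    "MEASURES",
    "COMM_MEASURES",
    "ExperimentConfig",
    "ExperimentResult",
    "trial_seed",
    "simulate_trial",
    "analyze_trial",
    "run_experiment",
    "summarize",
]

# fixed cell order: (target_number, visibility, perturbation)
CELLS: list[tuple[int, str, str]] = [
    (tn, vis, pert)
    for tn in (9, 18)
    for vis in ("clear", "fog")
    for pert in ("none", "late_spawn")
]

MEASURES = [
    "duration",
    "containment_rate",
    "overlap_proportion",
    "talk_operator",
    "talk_ground",
    "pct_rec_operator",
    "pct_det_operator",
    "pct_rec_ground",
    "pct_det_ground",
    "pct_rec_team",
    "pct_det_team",
]

COMM_MEASURES = [
    "talk_operator",
    "talk_ground",
    "pct_rec_operator",
    "pct_det_operator",
    "pct_rec_ground",
    "pct_det_ground",
    "pct_rec_team",
    "pct_det_team",
]

OUTCOMES = ["duration", "containment_rate"]


@dataclass
class ExperimentConfig:
    """Study-level configuration (defaults mirror the final-session protocol)."""

    n_teams: int = 10
    trials_per_cell: int = 2
    master_seed: int = 0
    shared_trial_order: bool = True  # every team runs the same shuffled order
    min_line: int = 2
    sim: SimParams = field(default_factory=SimParams)
    speech: SpeechParams = field(default_factory=SpeechParams)
    policy: PolicyParams = field(default_factory=PolicyParams)

    def __post_init__(self) -> None:
        if self.n_teams < 2:
            raise ValueError("n_teams must be >= 2 (the ANOVA needs >= 2 teams)")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")


def trial_seed(master_seed: int, team: int, cell: int, rep: int) -> int:
    """Order-independent child seed for one trial (31-bit)."""
    ss = np.random.SeedSequence([int(master_seed), int(team), int(cell), int(rep)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFF)


def _session_order(config: ExperimentConfig, team: int) -> list[tuple[int, int]]:
    entries = [
        (cell, rep)
        for rep in range(config.trials_per_cell)
        for cell in range(len(CELLS))
    ]
    key = [int(config.master_seed), 999_331]
    if not config.shared_trial_order:
        key.append(int(team))
    rng = np.random.default_rng(np.random.SeedSequence(key))
    rng.shuffle(entries)
    return entries


def simulate_trial(
    config: ExperimentConfig, team: int, cell: int, rep: int, trial_id: int = 0
) -> tuple[TrialRecord, SpeakerActivity]:
    """Simulate one trial's telemetry and matched speech series."""
    tn, vis, pert = CELLS[cell]
    seed = trial_seed(config.master_seed, team, cell, rep)
    design = ConditionDesign(
        target_number=tn,
        visibility=vis,
        perturbation=pert,
        trial_id=trial_id,
        team_id=team,
        seed=seed,
    )
    policy = ScriptedPolicy(config.policy)
    record = run_trial(design, policy=policy, params=config.sim, seed=seed)
    activity = generate_activity(
        record.duration, design, params=config.speech, seed=seed + 1
    )
    return record, activity


def analyze_trial(
    record: TrialRecord, activity: SpeakerActivity, min_line: int = 2
) -> dict:
    """All per-trial measures as one flat row."""
    design = record.design
    row = {
        "team_id": design.team_id,
        "trial_id": design.trial_id,
        "target_number": design.target_number,
        "visibility": design.visibility,
        "perturbation": design.perturbation,
        "seed": record.seed,
        "duration": record.duration,
        "success": record.success,
        "contained_at_end": record.contained_at_end,
        "containment_rate": containment_rate(record),
        "talk_operator": talk_proportion(activity, "operator"),
        "talk_ground": talk_proportion(activity, "ground"),
    }
    try:
        polys = [
            search_polygon(
                preprocess_trajectory(record.player_traj[i], record.params.tick_rate)
            )
            for i in range(record.player_traj.shape[0])
        ]
        ov = proportion_overlap(polys)
        row["overlap_proportion"] = ov.proportion
        row["overlap_area_m2"] = ov.overlap_area
        row["total_area_m2"] = ov.total_area
        row["polygon_methods"] = "|".join(p.method for p in polys)
    except (DegenerateGeometryError, ValueError):
        row["overlap_proportion"] = np.nan
        row["overlap_area_m2"] = np.nan
        row["total_area_m2"] = np.nan
        row["polygon_methods"] = "degenerate"
    for level in ("operator", "ground", "team"):
        res = catrqa_trial(activity, level, min_line=min_line)
        row[f"pct_rec_{level}"] = res.pct_rec
        row[f"pct_det_{level}"] = res.pct_det
        row[f"n_recurrent_{level}"] = res.n_recurrent
    return row


@dataclass
class ExperimentResult:
    """Bundle of per-trial rows, condition summaries, and fitted models."""

    config: ExperimentConfig
    trials: pd.DataFrame
    summary: pd.DataFrame
    anovas: pd.DataFrame
    regressions: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.anovas.to_csv(out / "anovas.csv", index=False)
        self.regressions.to_csv(out / "regressions.csv", index=False)


def run_experiment(
    config: Optional[ExperimentConfig] = None, progress: bool = False
) -> ExperimentResult:
    """Simulate and analyze the full synthetic study."""
    config = config or ExperimentConfig()
    rows = []
    for team in range(config.n_teams):
        order = _session_order(config, team)
        for trial_id, (cell, rep) in enumerate(order, start=1):
            record, activity = simulate_trial(config, team, cell, rep, trial_id)
            rows.append(analyze_trial(record, activity, min_line=config.min_line))
            if progress:
                print(
                    f"team {team} trial {trial_id:2d} "
                    f"{CELLS[cell]} dur={record.duration:6.1f}s "
                    f"success={record.success}"
                )
    trials = pd.DataFrame(rows)
    return ExperimentResult(
        config=config,
        trials=trials,
        summary=summarize(trials),
        anovas=_fit_anovas(trials),
        regressions=_fit_regressions(trials),
    )


def summarize(trials: pd.DataFrame, measures: Optional[list[str]] = None) -> pd.DataFrame:
    """Mean / SD / SE per measure and condition cell, long format."""
    if trials.empty:
        raise ValueError("no trials to summarize")
    measures = measures or [m for m in MEASURES if m in trials.columns]
    keys = ["target_number", "visibility", "perturbation"]
    rows = []
    for cell_values, grp in trials.groupby(keys, sort=True):
        for m in measures:
            vals = grp[m].dropna().to_numpy(dtype=float)
            n = len(vals)
            mean = vals.mean() if n else np.nan
            sd = vals.std(ddof=1) if n > 1 else np.nan
            rows.append(
                dict(
                    zip(keys, cell_values),
                    measure=m,
                    n=n,
                    mean=mean,
                    sd=sd,
                    se=sd / np.sqrt(n) if n > 1 else np.nan,
                )
            )
    return pd.DataFrame(rows)


def _fit_anovas(trials: pd.DataFrame) -> pd.DataFrame:
    tables = []
    for m in MEASURES:
        if m not in trials.columns or trials[m].dropna().empty:
            continue
        try:
            tab = rm_anova_2x2x2(trials.dropna(subset=[m]), dv=m).reset_index()
        except ValueError:
            continue  # a measure with empty cells (e.g. degenerate overlap)
        tab.insert(0, "measure", m)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def _design_matrix(trials: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    a = np.where(trials["target_number"].to_numpy() == 18, 0.5, -0.5)
    b = np.where(trials["visibility"].to_numpy() == "fog", 0.5, -0.5)
    c = np.where(trials["perturbation"].to_numpy() == "late_spawn", 0.5, -0.5)
    cols = {
        "target_number": a,
        "visibility": b,
        "perturbation": c,
        "target_number:visibility": a * b,
        "target_number:perturbation": a * c,
        "visibility:perturbation": b * c,
        "target_number:visibility:perturbation": a * b * c,
    }
    return np.column_stack(list(cols.values())), list(cols)


def _fit_regressions(trials: pd.DataFrame) -> pd.DataFrame:
    X, names = _design_matrix(trials)
    rows = []
    for outcome in OUTCOMES:
        y = trials[outcome].to_numpy(dtype=float)
        for comm in COMM_MEASURES:
            z = trials[comm].to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(z)
            try:
                res = mixed_regression(
                    y[ok], X[ok], z[ok], trials["team_id"].to_numpy()[ok], names
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            rows.append(
                {
                    "outcome": outcome,
                    "communication_measure": comm,
                    "beta": res.beta_z,
                    "se": res.se,
                    "z": res.zstat,
                    "p": res.pvalue,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "cohens_f2": res.cohens_f2,
                    "group_var": res.group_var,
                    "resid_var": res.resid_var,
                }
            )
    return pd.DataFrame(rows)
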