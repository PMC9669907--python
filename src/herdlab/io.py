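"""Plain-text interchange: tidy telemetry/speech CSVs and JSON configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from types import SimpleNamespace
from typing import Optional

import numpy as np
import pandas as pd

from .policy import PolicyParams
from .sim import STATUS_NAMES, ConditionDesign, SimParams, TrialRecord
from .speech import SPEAKERS, SpeakerActivity, SpeechParams

__all__ = [  # noqa: F822
    "trajectory_frame",
    "write_trial",
    "read_trial",
    "trial_summary",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
]



def trajectory_frame(record: TrialRecord, include_tas: bool = True) -> pd.DataFrame:
    """Tidy per-tick telemetry: one row per agent per tick."""
    t = record.times
    frames = []
    for i in range(record.player_traj.shape[0]):
        frames.append(
            pd.DataFrame(
                {
                    "team_id": record.design.team_id,
                    "trial_id": record.design.trial_id,
                    "t_seconds": t,
                    "agent_id": f"player{i + 1}",
                    "role": "ground",
                    "x_m": record.player_traj[i, :, 0],
                    "y_m": record.player_traj[i, :, 1],
                    "status": "active",
                }
            )
        )
    if include_tas:
        for j in range(record.n_tas):
            status = [STATUS_NAMES[int(s)] for s in record.ta_status[j]]
            frames.append(
                pd.DataFrame(
                    {
                        "team_id": record.design.team_id,
                        "trial_id": record.design.trial_id,
                        "t_seconds": t,
                        "agent_id": f"ta{j + 1}",
                        "role": "target_agent",
                        "x_m": record.ta_traj[j, :, 0],
                        "y_m": record.ta_traj[j, :, 1],
                        "status": status,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def trial_summary(record: TrialRecord) -> dict:
    d = record.design
    return {
        "team_id": d.team_id,
        "trial_id": d.trial_id,
        "target_number": d.target_number,
        "visibility": d.visibility,
        "perturbation": d.perturbation,
        "seed": record.seed,
        "duration": record.duration,
        "success": record.success,
        "contained_at_end": record.contained_at_end,
        "tick_rate": record.params.tick_rate,
    }


def write_trial(
    record: TrialRecord,
    activity: Optional[SpeakerActivity],
    outdir: str | Path,
    stem: str,
    include_tas: bool = False,
) -> None:
    """Write one trial as <stem>_telemetry.csv, <stem>_speech.csv, <stem>.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    trajectory_frame(record, include_tas=include_tas).to_csv(
        out / f"{stem}_telemetry.csv", index=False
    )
    if activity is not None:
        activity.to_frame().to_csv(out / f"{stem}_speech.csv", index=False)
    (out / f"{stem}.json").write_text(json.dumps(trial_summary(record), indent=2))


def read_trial(outdir: str | Path, stem: str):
    """Load a written trial back as (trial_data, activity).

    ``trial_data`` is a lightweight namespace with the fields the analysis
    layer needs (design, params echo, player_traj, duration, success,
    contained_at_end); TA telemetry is not required.
    """
    out = Path(outdir)
    meta = json.loads((out / f"{stem}.json").read_text())
    tele = pd.read_csv(out / f"{stem}_telemetry.csv")
    players = sorted(
        a for a in tele["agent_id"].unique() if str(a).startswith("player")
    )
    traj = np.stack(
        [
            tele.loc[tele["agent_id"] == a, ["x_m", "y_m"]].to_numpy(dtype=float)
            for a in players
        ]
    )
    design = ConditionDesign(
        target_number=int(meta["target_number"]),
        visibility=meta["visibility"],
        perturbation=meta["perturbation"],
        trial_id=meta["trial_id"],
        team_id=meta["team_id"],
        seed=int(meta["seed"]),
    )
    trial_data = SimpleNamespace(
        design=design,
        params=SimpleNamespace(tick_rate=meta["tick_rate"]),
        seed=int(meta["seed"]),
        player_traj=traj,
        duration=float(meta["duration"]),
        success=bool(meta["success"]),
        contained_at_end=int(meta["contained_at_end"]),
    )
    speech_path = out / f"{stem}_speech.csv"
    activity = None
    if speech_path.exists():
        sp = pd.read_csv(speech_path)
        if len(sp) < 2:
            frame_rate = 30.0
        else:
            frame_rate = 1.0 / (sp["t_seconds"].iloc[1] - sp["t_seconds"].iloc[0])
            if abs(frame_rate - round(frame_rate)) < 1e-6:
                frame_rate = float(round(frame_rate))
        activity = SpeakerActivity(
            sp[list(SPEAKERS)].to_numpy(dtype=np.int8),
            frame_rate=frame_rate,
            duration=float(meta["duration"]),
        )
    return trial_data, activity


# ---------------------------------------------------------------------------
# JSON configuration
# ---------------------------------------------------------------------------

_KEY_SEP = "|"


def _encode_keys(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        key = _KEY_SEP.join(str(x) for x in k) if isinstance(k, tuple) else str(k)
        out[key] = list(v) if isinstance(v, tuple) else v
    return out


def _decode_speech_keys(d: dict, arity: int) -> dict:
    out = {}
    for k, v in d.items():
        parts = k.split(_KEY_SEP)
        if len(parts) != arity:
            raise ValueError(f"bad speech config key {k!r}")
        key = []
        for p in parts:
            if p in ("True", "False"):
                key.append(p == "True")
            else:
                try:
                    key.append(int(p))
                except ValueError:
                    key.append(p)
        out[tuple(key)] = tuple(v) if isinstance(v, list) else v
    return out


def config_to_dict(config) -> dict:
    """Serialize an ExperimentConfig (or params dataclass) to JSON-safe dict."""
    from .experiment import ExperimentConfig

    if isinstance(config, ExperimentConfig):
        return {
            "schema_version": 1,
            "n_teams": config.n_teams,
            "trials_per_cell": config.trials_per_cell,
            "master_seed": config.master_seed,
            "shared_trial_order": config.shared_trial_order,
            "min_line": config.min_line,
            "sim": dataclasses.asdict(config.sim),
            "policy": dataclasses.asdict(config.policy),
            "speech": {
                **{
                    k: v
                    for k, v in dataclasses.asdict(config.speech).items()
                    if k not in ("mean_on", "talk_targets")
                },
                "mean_on": _encode_keys(dict(config.speech.mean_on)),
                "talk_targets": _encode_keys(dict(config.speech.talk_targets)),
            },
        }
    return dataclasses.asdict(config)


def config_from_dict(d: dict):
    """Build an ExperimentConfig from a (possibly partial) JSON dict."""
    from .experiment import ExperimentConfig

    d = dict(d)
    d.pop("schema_version", None)
    sim = SimParams(**d.pop("sim", {}))
    policy_kwargs = d.pop("policy", {})
    if "sweep_radii" in policy_kwargs:
        policy_kwargs["sweep_radii"] = tuple(policy_kwargs["sweep_radii"])
    policy = PolicyParams(**policy_kwargs)
    speech_kwargs = dict(d.pop("speech", {}))
    if "mean_on" in speech_kwargs:
        speech_kwargs["mean_on"] = _decode_speech_keys(speech_kwargs["mean_on"], 2)
    if "talk_targets" in speech_kwargs:
        speech_kwargs["talk_targets"] = _decode_speech_keys(
            speech_kwargs["talk_targets"], 4
        )
    speech = SpeechParams(**speech_kwargs)
    return ExperimentConfig(sim=sim, policy=policy, speech=speech, **d)


def load_config(path: str | Path):
    return config_from_dict(json.loads(Path(path).read_text()))


def save_config(config, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_dict(config), indent=2))
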