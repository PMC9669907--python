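"""Synthetic multi-speaker talk/silence series.

Stands in for voice-activity-detection output: one binary series per speaker
(one drone operator, three ground players) at 30 Hz frames.  Each speaker is
an alternating-renewal on/off process with exponential bout durations whose
long-run on-fraction is calibrated to a condition- and role-dependent target
talk-time table (normalized talk time, nTT).  A single coupling parameter
adds conversational structure: while someone else holds the floor a
speaker's onset hazard is suppressed (turn-taking inhibition), and for a
short window after the operator stops talking the ground players' onset
hazard is boosted (command/acknowledgement responses).  At ``coupling = 0``
the four speakers are exactly independent renewal processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .sim import ConditionDesign

__all__ = [
    "SPEAKERS",
    "SpeechParams",
    "SpeakerActivity",
    "generate_activity",
    "default_talk_targets",
]

SPEAKERS = ("operator", "gp1", "gp2", "gp3")

# (role, visibility, target_number, perturbed) -> (mean nTT, between-trial SD)
_TALK_TARGETS: dict[tuple[str, str, int, bool], tuple[float, float]] = {
    ("operator", "fog", 9, True): (0.59, 0.11),
    ("operator", "fog", 18, True): (0.63, 0.11),
    ("operator", "fog", 9, False): (0.63, 0.11),
    ("operator", "fog", 18, False): (0.64, 0.11),
    ("operator", "clear", 9, True): (0.49, 0.14),
    ("operator", "clear", 18, True): (0.22, 0.10),
    ("operator", "clear", 9, False): (0.51, 0.15),
    ("operator", "clear", 18, False): (0.47, 0.16),
    ("ground", "fog", 9, True): (0.20, 0.08),
    ("ground", "fog", 18, True): (0.19, 0.08),
    ("ground", "fog", 9, False): (0.19, 0.08),
    ("ground", "fog", 18, False): (0.20, 0.08),
    ("ground", "clear", 9, True): (0.22, 0.10),
    ("ground", "clear", 18, True): (0.24, 0.11),
    ("ground", "clear", 9, False): (0.21, 0.10),
    ("ground", "clear", 18, False): (0.24, 0.11),
}

# mean utterance (on-bout) duration in seconds per (role, visibility): under
# fog the operator issues longer directive utterances; ground players produce
# short callouts/acknowledgements throughout
_MEAN_ON = {
    ("operator", "fog"): 2.0,
    ("operator", "clear"): 1.2,
    ("ground", "fog"): 0.8,
    ("ground", "clear"): 0.8,
}


def default_talk_targets() -> dict[tuple[str, str, int, bool], tuple[float, float]]:
    return dict(_TALK_TARGETS)


@dataclass
class SpeechParams:
    """Generator configuration.

    ``talk_targets`` maps (role, visibility, target_number, perturbed) to a
    (mean, sd) pair of per-trial talk proportions; sd is between-trial jitter
    scaled by ``target_jitter`` (set 0 for exact targets).  ``coupling`` in
    [0, 1] is the master conversational-structure knob: onset hazards are
    multiplied by ``1 - coupling`` while another speaker is active, and
    ground-player onset hazards by ``1 + coupling * response_hazard_boost``
    for ``response_window`` seconds after an operator offset.
    """

    frame_rate: float = 30.0
    mean_on: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_MEAN_ON)
    )
    talk_targets: Mapping[tuple[str, str, int, bool], tuple[float, float]] = field(
        default_factory=default_talk_targets
    )
    target_jitter: float = 1.0
    coupling: float = 0.5
    response_hazard_boost: float = 1.5
    response_window: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.response_hazard_boost < 0:
            raise ValueError("response_hazard_boost must be >= 0")
        for key, value in self.mean_on.items():
            if value <= 0:
                raise ValueError(f"mean_on[{key}] must be > 0")
        for key, (mean, sd) in self.talk_targets.items():
            if not 0.0 <= mean < 1.0:
                raise ValueError(f"talk target mean for {key} must lie in [0, 1)")
            if sd < 0:
                raise ValueError(f"talk target sd for {key} must be >= 0")


@dataclass
class SpeakerActivity:
    """Frame-aligned binary speaking series, one column per speaker.

    ``data`` has shape (n_frames, 4) with 0 = silence, 1 = speaking, columns
    ordered (operator, gp1, gp2, gp3).
    """

    data: np.ndarray
    frame_rate: float
    duration: float
    speakers: tuple[str, ...] = SPEAKERS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.speakers):
            raise ValueError("data must be (n_frames, n_speakers)")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("activity values must be 0 or 1")
        expected = int(np.ceil(self.duration * self.frame_rate))
        if len(self.data) != expected:
            raise ValueError(
                f"expected {expected} frames for {self.duration}s at "
                f"{self.frame_rate} Hz, got {len(self.data)}"
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def operator(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def ground(self) -> np.ndarray:
        return self.data[:, 1:4]

    def proportion(self, speaker: str) -> float:
        return float(self.data[:, self.speakers.index(speaker)].mean())

    def to_frame(self) -> pd.DataFrame:
        n = len(self.data)
        df = pd.DataFrame(self.data, columns=list(self.speakers))
        df.insert(0, "t_seconds", np.arange(n) / self.frame_rate)
        df.insert(0, "frame_idx", np.arange(n))
        return df

    def to_intervals(self) -> pd.DataFrame:
        """Diarization-style speaker turns: (speaker, onset_s, offset_s)."""
        rows = []
        for j, name in enumerate(self.speakers):
            x = np.concatenate([[0], self.data[:, j], [0]])
            edges = np.flatnonzero(np.diff(x))
            for on, off in zip(edges[::2], edges[1::2]):
                rows.append((name, on / self.frame_rate, off / self.frame_rate))
        return pd.DataFrame(rows, columns=["speaker", "onset_s", "offset_s"])


def _role(speaker: str) -> str:
    return "operator" if speaker == "operator" else "ground"


def generate_activity(
    duration: float,
    condition: ConditionDesign,
    params: Optional[SpeechParams] = None,
    seed: Optional[int] = None,
    talk_proportions: Optional[Mapping[str, float]] = None,
) -> SpeakerActivity:
    """Simulate one trial's four-speaker talk/silence series.

    Per-speaker targets come from ``params.talk_targets`` for the trial's
    condition, jittered per trial by the configured between-trial SD;
    ``talk_proportions`` overrides them exactly (no jitter).  With
    ``params.coupling == 0`` every speaker is an independent exponential
    on/off renewal process whose realized talk fraction converges to its
    target as the trial lengthens.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    params = params or SpeechParams()
    rng = np.random.default_rng(seed)
    perturbed = condition.perturbation == "late_spawn"

    targets = np.empty(4)
    for j, name in enumerate(SPEAKERS):
        if talk_proportions is not None and name in talk_proportions:
            targets[j] = talk_proportions[name]
        else:
            mean, sd = params.talk_targets[
                (_role(name), condition.visibility, condition.target_number, perturbed)
            ]
            targets[j] = mean + params.target_jitter * sd * rng.standard_normal()
    if np.any(targets >= 1.0):
        raise ValueError(
            "talk proportion >= 1 is unreachable with a finite silence duration"
        )
    targets = np.clip(targets, 0.0, 0.95)

    mean_on = np.array(
        [params.mean_on[(_role(name), condition.visibility)] for name in SPEAKERS]
    )
    h_off = 1.0 / mean_on
    with np.errstate(divide="ignore"):
        h_on = np.where(
            targets > 0.0, targets / (mean_on * np.maximum(1.0 - targets, 1e-9)), 0.0
        )

    # first-order compensation so realized proportions track the targets even
    # with coupling active: the average onset-hazard multiplier for speaker i
    # is (1 - c * P(another speaker active)), times the response boost for
    # ground players over the expected fraction of time inside a response
    # window; divide the base hazard by it (exactly 1 when coupling = 0)
    c = params.coupling
    if c > 0.0:
        comp = np.empty(4)
        for j in range(4):
            others = np.delete(targets, j)
            q = 1.0 - np.prod(1.0 - others)
            comp[j] = 1.0 - c * q
        f_window = min(
            1.0,
            targets[0]
            / params.mean_on[("operator", condition.visibility)]
            * params.response_window,
        )
        comp[1:] *= 1.0 + c * params.response_hazard_boost * f_window
        h_on = h_on / np.maximum(comp, 1e-6)

    n = int(np.ceil(duration * params.frame_rate))
    dtf = 1.0 / params.frame_rate
    p_off = -np.expm1(-h_off * dtf)
    window_frames = int(round(params.response_window * params.frame_rate))
    boost = 1.0 + params.coupling * params.response_hazard_boost

    out = np.zeros((n, 4), dtype=np.int8)
    state = np.zeros(4, dtype=bool)
    u = rng.random((n, 4))
    response_timer = 0

    for k in range(n):
        any_active = state.any()
        others_active = state.sum() - state.astype(int) > 0 if any_active else np.zeros(4, bool)
        factor = np.where(others_active, 1.0 - params.coupling, 1.0)
        if response_timer > 0:
            factor[1:] *= boost
        p_on = -np.expm1(-h_on * factor * dtf)
        start = (~state) & (u[k] < p_on)
        stop = state & (u[k] < p_off)
        op_was_on = state[0]
        state = (state | start) & ~stop
        if op_was_on and not state[0]:
            response_timer = window_frames
        elif response_timer > 0:
            response_timer -= 1
        out[k] = state

    return SpeakerActivity(out, frame_rate=params.frame_rate, duration=float(duration))
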