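"""Scalar per-trial team measures.

All completed trials, successful or not, enter analysis; failed trials carry
the 300 s ceiling duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .overlap import OverlapResult
from .sim import ConditionDesign, TrialRecord
from .speech import SpeakerActivity

__all__ = ["TrialMetrics", "containment_rate", "talk_proportion", "trial_metrics"]


@dataclass
class TrialMetrics:
    design: ConditionDesign
    duration: float
    success: bool
    contained_at_end: int
    containment_rate: float
    talk_operator: float
    talk_ground_mean: float
    overlap_proportion: Optional[float] = None


def containment_rate(record: TrialRecord) -> float:
    """TAs contained at trial end per second of trial (higher is better)."""
    if record.duration <= 0:
        raise ValueError("trial duration must be > 0")
    return record.contained_at_end / record.duration


def talk_proportion(activity: SpeakerActivity, role: str) -> float:
    """Fraction of the trial a role spent speaking.

    ``"operator"`` returns the operator's own proportion; ``"ground"`` the
    arithmetic mean of the three ground players' proportions.
    """
    if len(activity) == 0:
        raise ValueError("activity series is empty")
    if role == "operator":
        return float(activity.operator.mean())
    if role == "ground":
        per_player = activity.ground.mean(axis=0)
        return float(per_player.mean())
    raise ValueError("role must be 'operator' or 'ground'")


def trial_metrics(
    record: TrialRecord,
    activity: SpeakerActivity,
    overlap: Optional[OverlapResult] = None,
) -> TrialMetrics:
    return TrialMetrics(
        design=record.design,
        duration=record.duration,
        success=record.success,
        contained_at_end=record.contained_at_end,
        containment_rate=containment_rate(record),
        talk_operator=talk_proportion(activity, "operator"),
        talk_ground_mean=talk_proportion(activity, "ground"),
        overlap_proportion=None if overlap is None else overlap.proportion,
    )
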