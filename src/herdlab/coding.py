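"""Categorical coding of speaker activity for recurrence analysis.

Three coding levels:

* ``operator`` — the operator's own binary series (1 speaking, 0 silence);
* ``ground``  — 0 silence, 1-3 the single speaking ground player, 4 two or
  more ground players at once (the operator channel is ignored);
* ``team``    — 0 silence, 1 operator alone, 2-4 a single ground player,
  5 any two or more of the four speakers at once.

Silence must never count as a recurrence, so before RQA every 0-frame is
recoded with a unique non-repeating label (a strictly decreasing negative
counter — deterministic, disjoint from every coding alphabet, and incapable
of recurring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .speech import SpeakerActivity

__all__ = [
    "CategoricalSeries",
    "code_operator",
    "code_ground",
    "code_team",
    "recode_silence",
    "code_level",
]

LEVELS = ("operator", "ground", "team")
ALPHABETS = {
    "operator": (1,),
    "ground": (1, 2, 3, 4),
    "team": (1, 2, 3, 4, 5),
}


@dataclass
class CategoricalSeries:
    """Integer-coded frame series at one coding level."""

    codes: np.ndarray
    level: str
    recoded: bool = False
    alphabet: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        if not self.alphabet:
            self.alphabet = ALPHABETS[self.level]
        if not self.recoded:
            allowed = set(self.alphabet) | {0}
            bad = set(np.unique(self.codes)) - allowed
            if bad:
                raise ValueError(f"codes {sorted(bad)} outside alphabet for {self.level}")

    def __len__(self) -> int:
        return len(self.codes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"frame_idx": np.arange(len(self.codes)), "code": self.codes}
        )
        df["level"] = self.level
        df["recoded"] = self.recoded
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CategoricalSeries":
        """Inverse of :meth:`to_frame` (CSV round trip)."""
        df = df.sort_values("frame_idx")
        return cls(
            df["code"].to_numpy(dtype=np.int64),
            level=str(df["level"].iloc[0]),
            recoded=bool(df["recoded"].iloc[0]),
        )


def code_operator(activity: SpeakerActivity) -> CategoricalSeries:
    """Framewise copy of the operator channel (1 speaking / 0 silent)."""
    return CategoricalSeries(activity.operator.astype(np.int64), "operator")


def code_ground(activity: SpeakerActivity) -> CategoricalSeries:
    """Ground-player coding: lone speaker k -> k, none -> 0, two or more -> 4."""
    gp = activity.ground
    n_active = gp.sum(axis=1)
    solo = gp.argmax(axis=1) + 1  # valid only where exactly one speaks
    codes = np.where(n_active == 0, 0, np.where(n_active >= 2, 4, solo))
    return CategoricalSeries(codes.astype(np.int64), "ground")


def code_team(activity: SpeakerActivity) -> CategoricalSeries:
    """Team coding: operator alone -> 1, gp_k alone -> k+1, overlap -> 5."""
    data = activity.data
    n_active = data.sum(axis=1)
    solo = data.argmax(axis=1) + 1  # operator column first, so op -> 1, gp_k -> k+1
    codes = np.where(n_active == 0, 0, np.where(n_active >= 2, 5, solo))
    return CategoricalSeries(codes.astype(np.int64), "team")


def code_level(activity: SpeakerActivity, level: str) -> CategoricalSeries:
    coder = {"operator": code_operator, "ground": code_ground, "team": code_team}
    if level not in coder:
        raise ValueError(f"level must be one of {LEVELS}")
    return coder[level](activity)


def recode_silence(
    series: CategoricalSeries, rng: Optional[np.random.Generator] = None
) -> CategoricalSeries:
    """Replace every silence frame with a unique, never-recurring code.

    Codes are drawn from a strictly decreasing negative counter; ``rng`` is
    accepted for interface compatibility but unused — only non-repetition
    matters downstream, and a deterministic counter aids reproducibility.
    """
    if series.recoded:
        raise ValueError("series is already silence-recoded")
    codes = series.codes.copy()
    silent = codes == 0
    codes[silent] = -1 - np.arange(int(silent.sum()), dtype=np.int64)
    return CategoricalSeries(
        codes, series.level, recoded=True, alphabet=series.alphabet
    )
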