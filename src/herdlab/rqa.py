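"""Categorical recurrence quantification (%REC, %DET).

A categorical auto-recurrence plot marks (i, j), i != j, wherever the coded
series takes exactly the same value at both frames (embedding dimension 1,
delay 1, no radius).  The line of identity is excluded from both the
numerator and the ``n^2 - n`` denominator by default.

%REC is the percentage of off-diagonal cells that are recurrent; %DET the
percentage of recurrent points lying on diagonal line segments of at least
``min_line`` points — repeated *sequences* of states.  %DET of an empty plot
is defined as 0 so condition averages never drop trials.

The heavy statistics never materialize the n x n matrix: recurrent points
are counted from code multiplicities, and diagonal lines are run-length
encoded per diagonal offset against the shifted series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .coding import CategoricalSeries, code_level, recode_silence
from .speech import SpeakerActivity

__all__ = [
    "RecurrencePlot",
    "RQAResult",
    "recurrence_plot",
    "percent_recurrence",
    "percent_determinism",
    "catrqa_trial",
]


@dataclass
class RecurrencePlot:
    """Auto-recurrence structure of one coded series."""

    codes: np.ndarray
    loi_excluded: bool = True
    _hist: Optional[dict[int, int]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 1 or len(self.codes) < 2:
            raise ValueError("recurrence plot needs a 1-D series of length >= 2")

    @property
    def n(self) -> int:
        return len(self.codes)

    @property
    def n_recurrent(self) -> int:
        """Number of recurrent points (both triangles, LOI excluded if set)."""
        _, counts = np.unique(self.codes, return_counts=True)
        total = int((counts.astype(np.int64) ** 2).sum())
        return total - self.n if self.loi_excluded else total

    def line_histogram(self) -> dict[int, int]:
        """Diagonal line-length histogram over all off-LOI diagonals.

        Both triangles are counted (the plot is symmetric), so every entry is
        even; ``sum(L * count)`` over all L equals ``n_recurrent``.
        """
        if self._hist is None:
            hist: dict[int, int] = {}
            c = self.codes
            for k in range(1, self.n):
                m = c[k:] == c[:-k]
                if not m.any():
                    continue
                padded = np.empty(len(m) + 2, dtype=np.int8)
                padded[0] = padded[-1] = 0
                padded[1:-1] = m
                edges = np.flatnonzero(np.diff(padded))
                lengths = edges[1::2] - edges[::2]
                for L in lengths:
                    hist[int(L)] = hist.get(int(L), 0) + 2
            self._hist = hist
        return dict(self._hist)

    def points(self) -> set[tuple[int, int]]:
        """Explicit recurrent-point set; intended for small series."""
        eq = self.codes[:, None] == self.codes[None, :]
        if self.loi_excluded:
            np.fill_diagonal(eq, False)
        ii, jj = np.nonzero(eq)
        return set(zip(ii.tolist(), jj.tolist()))


@dataclass
class RQAResult:
    """Summary statistics of one recurrence plot."""

    level: str
    n: int
    n_recurrent: int
    pct_rec: float
    pct_det: float
    min_line: int
    line_histogram: dict[int, int]


def recurrence_plot(
    series: Union[CategoricalSeries, np.ndarray], loi_excluded: bool = True
) -> RecurrencePlot:
    """Build the recurrence plot of a coded series.

    A :class:`CategoricalSeries` must already be silence-recoded (or contain
    no silence): raw 0-frames would recur against each other and fabricate
    structure out of shared silence.
    """
    if isinstance(series, CategoricalSeries):
        codes = series.codes
        if not series.recoded and np.any(codes == 0):
            raise ValueError(
                "series contains silence (code 0); apply recode_silence before RQA"
            )
    else:
        codes = np.asarray(series)
    return RecurrencePlot(codes, loi_excluded=loi_excluded)


def percent_recurrence(rp: RecurrencePlot) -> float:
    """%REC = 100 * recurrent points / (n^2 - n)."""
    if rp.n < 2:
        raise ValueError("%REC needs a series of length >= 2")
    denom = rp.n * rp.n - rp.n if rp.loi_excluded else rp.n * rp.n
    return 100.0 * rp.n_recurrent / denom


def percent_determinism(rp: RecurrencePlot, min_line: int = 2) -> float:
    """%DET = 100 * recurrent points on diagonal lines >= min_line / recurrent points."""
    if min_line < 2:
        raise ValueError("min_line must be >= 2")
    n_rec = rp.n_recurrent
    if n_rec == 0:
        return 0.0
    hist = rp.line_histogram()
    on_lines = sum(L * c for L, c in hist.items() if L >= min_line)
    return 100.0 * on_lines / n_rec


def catrqa_trial(
    activity: SpeakerActivity, level: str, min_line: int = 2
) -> RQAResult:
    """Code one trial's activity at ``level``, recode silence, and run catRQA."""
    series = recode_silence(code_level(activity, level))
    rp = recurrence_plot(series)
    return RQAResult(
        level=level,
        n=rp.n,
        n_recurrent=rp.n_recurrent,
        pct_rec=percent_recurrence(rp),
        pct_det=percent_determinism(rp, min_line=min_line),
        min_line=min_line,
        line_histogram=rp.line_histogram(),
    )
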