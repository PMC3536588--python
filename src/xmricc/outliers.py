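"""Bubble-chart dataset and the consecutive two-month outlier rule.

For one scored month, every case contributes a point at (current-month SD,
previous-month SD); bubble size is |current SD|.  A case whose two most
recent distances both exceed the threshold *with the same sign* — the
top-right or bottom-left quadrant outside the rectangular control area — has
a consecutive out-of-control effect and is flagged ``outlier``; any other
exceedance is a ``watch``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .xmr import SdScoreMatrix


@dataclass(frozen=True)
class BubblePoint:
    case_id: str
    sd_current: float
    sd_previous: float
    size: float
    flag: str = "none"


def bubble_points(scores: SdScoreMatrix, month: str) -> list[BubblePoint]:
    """One (current, previous) SD point per case for a scored month."""
    try:
        idx = scores.month_labels.index(month)
    except ValueError:
        raise ValueError(f"month {month!r} not in the score matrix") from None
    if idx <= scores.first_scored_index:
        raise ValueError(
            f"month {month!r} has no scored predecessor (burn-in or first scored month)"
        )
    cur = scores.sd_values[:, idx]
    prev = scores.sd_values[:, idx - 1]
    return [
        BubblePoint(case_id=cid, sd_current=float(c), sd_previous=float(p),
                    size=float(abs(c)))
        for cid, c, p in zip(scores.case_ids, cur, prev)
    ]


def flag_outliers(points: list[BubblePoint], threshold: float = 2.0) -> list[BubblePoint]:
    """Annotate points with the strict > threshold quadrant rule.

    outlier: both |coordinates| > threshold and same sign (consecutive effect);
    watch: any other exceedance (single month, or mixed signs);
    none: inside the rectangular control area.  Boundary equality does not
    trigger a flag.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = []
    for p in points:
        cur_out = abs(p.sd_current) > threshold
        prev_out = abs(p.sd_previous) > threshold
        if cur_out and prev_out and p.sd_current * p.sd_previous > 0:
            flag = "outlier"
        elif cur_out or prev_out:
            flag = "watch"
        else:
            flag = "none"
        out.append(replace(p, flag=flag))
    return out


def bubble_table(points: list[BubblePoint]) -> pd.DataFrame:
    """Plot-ready table: case_id, x (current), y (previous), size, flag."""
    return pd.DataFrame(
        {
            "case_id": [p.case_id for p in points],
            "x": [p.sd_current for p in points],
            "y": [p.sd_previous for p in points],
            "size": [p.size for p in points],
            "flag": [p.flag for p in points],
        }
    )
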