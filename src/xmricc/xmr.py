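"""Sequential XmR (individuals / moving-range) scoring of monthly series.

Each month is compared against a trailing baseline window (default: the 12
previous months).  The process sigma is the individuals-chart estimate
``mean moving range / 1.128`` (d2 for subgroups of size 2), the centre line
is the window mean, and the signed distance ``(x - CL) / sigma`` is recorded
and then discretized into ordinal SD bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpenditureMatrix

#: d2 bias-correction constant for moving ranges of two consecutive points.
D2 = 1.128

#: band cap: distances are gauged in the range -4 .. +4
BAND_CAP = 4


@dataclass(frozen=True)
class BaselineStats:
    """Centre line and process sigma of one trailing baseline window."""

    center_line: float
    sigma: float
    window_length: int

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("baseline window needs at least 2 points")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class SdScoreMatrix:
    """Cases x months grid of signed SD distances plus their band codes.

    Full-width layout: all input month labels are retained; the first
    ``first_scored_index`` columns are burn-in and hold NaN in both grids.
    """

    case_ids: list[str]
    month_labels: list[str]
    sd_values: np.ndarray
    band_codes: np.ndarray
    first_scored_index: int
    scheme: str = "ten_band"

    def __post_init__(self) -> None:
        self.sd_values = np.asarray(self.sd_values, dtype=float)
        self.band_codes = np.asarray(self.band_codes, dtype=float)
        if self.sd_values.shape != self.band_codes.shape:
            raise ValueError("sd_values and band_codes must share a shape")
        if self.sd_values.shape != (len(self.case_ids), len(self.month_labels)):
            raise ValueError("grid shape does not match ids/labels")
        if not np.array_equal(np.isnan(self.sd_values), np.isnan(self.band_codes)):
            raise ValueError("sd_values and band_codes must share a missingness pattern")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def scored_labels(self) -> list[str]:
        return self.month_labels[self.first_scored_index:]


def baseline_stats(window) -> BaselineStats:
    """Centre line and sigma of a trailing window of individual values.

    sigma = (mean absolute successive difference) / 1.128.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("baseline window must be 1-D with at least 2 values")
    mr_bar = float(np.mean(np.abs(np.diff(w))))
    return BaselineStats(center_line=float(w.mean()), sigma=mr_bar / D2,
                         window_length=int(w.size))


def xmr_score(value: float, baseline: BaselineStats, cap: float = BAND_CAP) -> float:
    """Signed distance of ``value`` from the centre line in sigma units.

    A degenerate (zero-sigma) baseline cannot scale a deviation, so any
    off-centre value is capped at the band extreme rather than aborting the
    scan; an on-centre value scores 0.  "On-centre" allows a relative
    tolerance of 1e-9 so that a constant series whose window mean picks up
    float rounding still scores 0.
    """
    d = value - baseline.center_line
    if baseline.sigma == 0.0:
        if np.isclose(value, baseline.center_line, rtol=1e-9, atol=1e-12):
            return 0.0
        return float(np.sign(d) * cap)
    return float(d / baseline.sigma)


def discretize(sd, scheme: str = "ten_band", zero_band: int = 1):
    """Map signed SD distances to ordinal band codes (scalar or array).

    ten_band
        ``sign(sd) * min(4, ceil(|sd|))`` giving codes in {-4..-1, +1..+4};
        sd exactly 0 sits between the "<0" and ">0" bands and is assigned
        ``zero_band`` (+1 by default, configurable to -1).
    five_band
        round half away from zero, clip to [-2, 2], shift to {0..4}.

    NaN passes through (burn-in cells).
    """
    arr = np.asarray(sd, dtype=float)
    nan = np.isnan(arr)
    if scheme == "ten_band":
        if zero_band not in (-1, 1):
            raise ValueError("zero_band must be +1 or -1")
        with np.errstate(invalid="ignore"):
            code = np.sign(arr) * np.minimum(BAND_CAP, np.ceil(np.abs(arr)))
        code = np.where(~nan & (arr == 0.0), float(zero_band), code)
    elif scheme == "five_band":
        with np.errstate(invalid="ignore"):
            rounded = np.sign(arr) * np.floor(np.abs(arr) + 0.5)
        code = np.clip(rounded, -2, 2) + 2
    else:
        raise ValueError(f"unknown band scheme {scheme!r}")
    code = np.where(nan, np.nan, code)
    if np.ndim(sd) == 0:
        return float(code) if np.isnan(code) else int(code)
    return code


def sequential_scan(matrix: ExpenditureMatrix, baseline_length: int = 12,
                    scheme: str = "ten_band", zero_band: int = 1,
                    cap: float = BAND_CAP) -> SdScoreMatrix:
    """Score every month >= ``baseline_length`` against its trailing window.

    Row-independent: each case's series is scanned on its own.  The first
    ``baseline_length`` columns are burn-in (NaN scores).
    """
    x = matrix.values
    n, k = x.shape
    if k < baseline_length + 1:
        raise ValueError(
            f"need at least baseline_length+1={baseline_length + 1} columns, got {k}"
        )
    sd = np.full((n, k), np.nan)
    for t in range(baseline_length, k):
        window = x[:, t - baseline_length:t]
        center = window.mean(axis=1)
        sigma = np.abs(np.diff(window, axis=1)).mean(axis=1) / D2
        d = x[:, t] - center
        with np.errstate(divide="ignore", invalid="ignore"):
            score = d / sigma
        degenerate = sigma == 0.0
        # same zero-sigma convention as xmr_score, with its on-centre tolerance
        on_centre = np.isclose(x[:, t], center, rtol=1e-9, atol=1e-12)
        score[degenerate] = np.where(on_centre[degenerate], 0.0,
                                     np.sign(d[degenerate]) * cap)
        sd[:, t] = score
    bands = discretize(sd, scheme=scheme, zero_band=zero_band)
    return SdScoreMatrix(
        case_ids=list(matrix.case_ids),
        month_labels=list(matrix.month_labels),
        sd_values=sd,
        band_codes=bands,
        first_scored_index=baseline_length,
        scheme=scheme,
    )
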