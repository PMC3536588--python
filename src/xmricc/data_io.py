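"""Wide-matrix I/O and calendar-year slicing.

The canonical interchange format is a wide CSV: one row per monitored case
(hospital, provider, ...), one column per consecutive calendar month, cells
holding reimbursed expenditure in an arbitrary monetary unit.  Rows with any
missing cell are excluded outright — a case that was closed, newly opened or
otherwise unobserved in some month cannot be scored against a trailing
baseline, so imputation is deliberately not offered.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


class FormatError(ValueError):
    """Malformed input: bad month headers, negative cells, parse failures."""


class AlignmentError(ValueError):
    """Scored region does not cover whole calendar years."""


class EmptyInputError(ValueError):
    """No complete rows survived the completeness filter."""


def parse_month(label: str) -> tuple[int, int]:
    """Parse an ISO ``YYYY-MM`` label into ``(year, month)``."""
    m = _MONTH_RE.match(str(label).strip())
    if not m:
        raise FormatError(f"month label {label!r} is not of the form YYYY-MM")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise FormatError(f"month label {label!r} has month outside 1..12")
    return year, month


def _check_consecutive(labels: list[str]) -> None:
    parsed = [parse_month(lab) for lab in labels]
    for (y0, m0), (y1, m1) in zip(parsed, parsed[1:]):
        expect = (y0, m0 + 1) if m0 < 12 else (y0 + 1, 1)
        if (y1, m1) != expect:
            raise FormatError(
                f"month headers must be strictly increasing consecutive months; "
                f"found {y0:04d}-{m0:02d} followed by {y1:04d}-{m1:02d}"
            )


def month_labels(start: str, n_months: int) -> list[str]:
    """Generate ``n_months`` consecutive ISO labels beginning at ``start``."""
    y, m = parse_month(start)
    out = []
    for _ in range(n_months):
        out.append(f"{y:04d}-{m:02d}")
        y, m = (y, m + 1) if m < 12 else (y + 1, 1)
    return out


@dataclass
class ExpenditureMatrix:
    """Cases x months grid of monthly monetary amounts.

    ``values`` is a dense float array with no missing cells; incomplete rows
    are dropped at read time and counted in ``n_dropped``.
    """

    case_ids: list[str]
    month_labels: list[str]
    values: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D cases x months grid")
        if self.values.shape != (len(self.case_ids), len(self.month_labels)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.case_ids)} cases x {len(self.month_labels)} months"
            )
        if np.isnan(self.values).any():
            raise FormatError("ExpenditureMatrix cells must be complete (no NaN)")
        _check_consecutive(self.month_labels)

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_months(self) -> int:
        return len(self.month_labels)


@dataclass(frozen=True)
class YearBlock:
    """The 12 column indices of one calendar year inside a score matrix."""

    year: int
    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.columns) != 12:
            raise AlignmentError(f"year {self.year}: expected 12 columns, got {len(self.columns)}")


def read_matrix(path, *, require_nonnegative: bool = True) -> ExpenditureMatrix:
    """Read a wide CSV (first column = case id, remaining headers = YYYY-MM).

    Rows with any missing/blank cell are dropped and counted; the retained
    matrix satisfies the :class:`ExpenditureMatrix` invariants.
    """
    df = pd.read_csv(path, dtype={0: str}, index_col=0, thousands=None)
    labels = [str(c) for c in df.columns]
    _check_consecutive(labels)  # raises FormatError on bad headers
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    complete = ~np.isnan(vals).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows of %d", n_dropped, len(df))
    if not complete.any():
        raise EmptyInputError(f"no complete rows in {path}")
    vals = vals[complete]
    if require_nonnegative and (vals < 0).any():
        raise FormatError("expenditure cells must be non-negative")
    ids = [str(i) for i in df.index[complete]]
    return ExpenditureMatrix(ids, labels, vals, n_dropped=n_dropped)


def write_matrix(matrix: ExpenditureMatrix, path) -> None:
    """Write an :class:`ExpenditureMatrix` back to wide CSV."""
    pd.DataFrame(matrix.values, index=pd.Index(matrix.case_ids, name="id"),
                 columns=matrix.month_labels).to_csv(path)


def write_scores(scores, sd_path, bands_path) -> None:
    """Serialize a score matrix as two wide CSVs: SD distances and band codes.

    Burn-in (missing) cells are written as empty strings; SD values keep six
    decimals, band codes are integers.  ``read_scores`` round-trips both.
    """
    if scores.sd_values.size == 0:
        raise EmptyInputError("refusing to write an empty score matrix")
    idx = pd.Index(scores.case_ids, name="id")
    sd = pd.DataFrame(np.round(scores.sd_values, 6), index=idx, columns=scores.month_labels)
    sd.to_csv(sd_path, na_rep="")
    bands = pd.DataFrame(scores.band_codes, index=idx, columns=scores.month_labels)
    # integer band codes with empty strings for burn-in
    bands = bands.map(lambda v: "" if np.isnan(v) else str(int(v)))
    bands.to_csv(bands_path)


def read_scores(sd_path, bands_path):
    """Re-read the two score CSVs written by :func:`write_scores`."""
    from .xmr import SdScoreMatrix  # local import: xmr depends on this module

    sd = pd.read_csv(sd_path, dtype={0: str}, index_col=0)
    bands = pd.read_csv(bands_path, dtype={0: str}, index_col=0)
    if list(sd.index) != list(bands.index) or list(sd.columns) != list(bands.columns):
        raise FormatError("sd and band files disagree on cases or months")
    sd_values = sd.to_numpy(dtype=float)
    band_codes = bands.to_numpy(dtype=float)
    burn = np.isnan(sd_values).all(axis=0)
    first_scored = int(np.argmin(burn)) if (~burn).any() else sd_values.shape[1]
    return SdScoreMatrix(
        case_ids=[str(i) for i in sd.index],
        month_labels=[str(c) for c in sd.columns],
        sd_values=sd_values,
        band_codes=band_codes,
        first_scored_index=first_scored,
    )


def yearly_blocks(labels: list[str], first_scored_index: int) -> list[YearBlock]:
    """Partition the scored region into whole-calendar-year 12-column blocks.

    The scored region (columns ``first_scored_index`` onward) must begin in a
    January and end in a December, else an :class:`AlignmentError` is raised.
    """
    _check_consecutive(labels)
    if not 0 <= first_scored_index < len(labels):
        raise AlignmentError("first_scored_index outside the label range")
    scored = labels[first_scored_index:]
    y0, m0 = parse_month(scored[0])
    y1, m1 = parse_month(scored[-1])
    if m0 != 1 or m1 != 12:
        raise AlignmentError(
            f"scored region {scored[0]}..{scored[-1]} is not aligned to whole "
            f"calendar years (must start in January and end in December)"
        )
    blocks = []
    for i, year in enumerate(range(y0, y1 + 1)):
        cols = tuple(range(first_scored_index + 12 * i, first_scored_index + 12 * (i + 1)))
        blocks.append(YearBlock(year=year, columns=cols))
    return blocks
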