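"""Scenario generators: Rasch rating-scale matrices, iid-normal nulls and
plausible monthly expenditure panels.

Five named calibration scenarios describe a panel of monitored cases over k
ordinal items (months).  A case's latent measure theta is either dispersed
(standard normal) or pinned at 0; item difficulties are either a linear ramp
or flat 0.  Cells are drawn from the rating-scale model

    P(X = j) ∝ exp( sum_{l<=j} (theta - delta - tau_l) ),   j = 0..m-1,

with shared, strictly increasing category thresholds tau.  The ``random_normal``
scenario instead fills the grid with iid N(0,1) continuous values — the
homogeneous-null benchmark whose ICC is centred on zero.

Two pipelines turn a scenario into an analysis matrix: ``direct`` uses the
sampled categories themselves, while ``xmr`` treats the sampled categories as
a monthly series, runs the sequential XmR scan over it and keeps the
five-band codes of the scored months.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import ExpenditureMatrix, month_labels
from .xmr import sequential_scan

SCENARIO_NAMES = ("increasing", "decreasing", "out_of_control", "in_control",
                  "random_normal")

#: difficulty ramps (first item -> last item, logits) per scenario
_DIFFICULTY = {
    "increasing": (2.0, -1.0),
    "decreasing": (-2.0, 1.0),
    "out_of_control": (0.0, 0.0),
    "in_control": (0.0, 0.0),
}

#: scenarios whose person measures are standard normal (vs pinned at 0)
_DISPERSED = {"increasing", "decreasing", "out_of_control", "random_normal"}


@dataclass(frozen=True)
class ScenarioSpec:
    """Generation recipe for one calibration scenario."""

    name: str
    n_persons: int = 421
    n_items: int = 13
    n_categories: int = 5
    thresholds: tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}")
        if len(self.thresholds) != self.n_categories - 1:
            raise ValueError("need n_categories - 1 thresholds")
        if any(a >= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        if self.n_persons < 1 or self.n_items < 1:
            raise ValueError("dimensions must be positive")

    @property
    def person_dist(self) -> str:
        return "normal" if self.name in _DISPERSED else "zero"

    def difficulties(self) -> np.ndarray:
        """Item difficulties: the scenario's linear ramp across n_items."""
        lo, hi = _DIFFICULTY.get(self.name, (0.0, 0.0))
        return np.linspace(lo, hi, self.n_items)


@dataclass(frozen=True)
class SimulatedMatrix:
    """A generated grid together with its recipe and seed (reproducible)."""

    values: np.ndarray
    spec: "ScenarioSpec | tuple"
    seed: int
    labels: tuple[str, ...] = ()


def rsm_probabilities(theta: float, delta: float, thresholds) -> np.ndarray:
    """Category probabilities of the rating-scale model at one person/item."""
    tau = np.asarray(thresholds, dtype=float)
    if (np.diff(tau) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    # cumulative sums of (theta - delta - tau_l); empty sum = 0 for category 0
    steps = theta - delta - tau
    logits = np.concatenate([[0.0], np.cumsum(steps)])
    logits -= logits.max()  # guard overflow
    w = np.exp(logits)
    return w / w.sum()


def expected_score(theta: float, delta: float, thresholds) -> float:
    """Model-implied mean category, strictly increasing in theta."""
    p = rsm_probabilities(theta, delta, thresholds)
    return float(np.dot(p, np.arange(p.size)))


def _row_rng(seed: int, row: int) -> np.random.Generator:
    # per-case substream: stable under changes of total row count
    return np.random.default_rng([int(seed), int(row)])


def generate_scenario_matrix(spec: ScenarioSpec, seed: int,
                             pipeline: str = "direct",
                             baseline_length: int = 12) -> SimulatedMatrix:
    """Draw one matrix for a scenario.

    ``pipeline="direct"`` returns the raw draws (categories, or continuous
    normals for ``random_normal``).  ``pipeline="xmr"`` generates a series of
    ``baseline_length + n_items`` months per case, scans it with the XmR
    routine and returns the five-band codes of the ``n_items`` scored months.
    """
    if pipeline not in ("direct", "xmr"):
        raise ValueError("pipeline must be 'direct' or 'xmr'")
    n_series = spec.n_items if pipeline == "direct" else baseline_length + spec.n_items
    if spec.name == "random_normal":
        rows = [_row_rng(seed, i).standard_normal(n_series)
                for i in range(spec.n_persons)]
        values = np.vstack(rows)
    else:
        lo, hi = _DIFFICULTY[spec.name]
        delta = np.linspace(lo, hi, n_series)
        cats = np.arange(spec.n_categories)
        values = np.empty((spec.n_persons, n_series))
        for i in range(spec.n_persons):
            rng = _row_rng(seed, i)
            theta = rng.standard_normal() if spec.person_dist == "normal" else 0.0
            for j in range(n_series):
                p = rsm_probabilities(theta, delta[j], spec.thresholds)
                values[i, j] = cats[rng.choice(spec.n_categories, p=p)]
    if pipeline == "xmr":
        em = ExpenditureMatrix(
            case_ids=[f"case{i}" for i in range(spec.n_persons)],
            month_labels=month_labels("1999-01", n_series),
            values=values,
        )
        scores = sequential_scan(em, baseline_length=baseline_length,
                                 scheme="five_band")
        values = scores.band_codes[:, baseline_length:]
    return SimulatedMatrix(values=values, spec=spec, seed=int(seed))


def combine_scenarios(spec_a: ScenarioSpec, spec_b: ScenarioSpec, seed: int,
                      pipeline: str = "direct") -> SimulatedMatrix:
    """Stack a 50/50 mixture of two scenarios (odd counts: extra row to A).

    Total rows equal ``spec_a.n_persons`` (both specs must agree on
    dimensions); rows from A come first, provenance kept in ``spec``.
    """
    if spec_a.n_items != spec_b.n_items:
        raise ValueError("scenarios must share n_items to be combined")
    if spec_a.n_persons != spec_b.n_persons:
        raise ValueError("scenarios must share n_persons; the total is split 50/50")
    total = spec_a.n_persons
    n_a = (total + 1) // 2
    n_b = total - n_a
    a = generate_scenario_matrix(replace(spec_a, n_persons=n_a), seed=2 * seed,
                                 pipeline=pipeline)
    b = generate_scenario_matrix(replace(spec_b, n_persons=n_b), seed=2 * seed + 1,
                                 pipeline=pipeline)
    return SimulatedMatrix(values=np.vstack([a.values, b.values]),
                           spec=(spec_a, spec_b), seed=int(seed))


@dataclass(frozen=True)
class Shock:
    """A known out-of-control excursion injected into one case's series.

    ``magnitude`` is in process-sigma units as the scanner will measure it;
    ``duration`` consecutive months are displaced (2 emulates the
    consecutive-effect signature the bubble chart flags).
    """

    case: int
    month: int
    magnitude: float
    duration: int = 1


def generate_expenditure_series(n_cases: int, n_months: int,
                                drift: float = 0.003, noise_cv: float = 0.05,
                                outlier_spec: "list[Shock] | None" = None,
                                seed: int = 0, base_level: float = 100.0,
                                baseline_length: int = 12,
                                start: str = "1999-01") -> ExpenditureMatrix:
    """Plausible positive monthly reimbursement panel for end-to-end demos.

    Each case gets a lognormal base level, a geometric ``drift`` per month and
    multiplicative noise with coefficient of variation ``noise_cv``.  Shocks
    are injected sequentially: the shocked value is set to exactly
    ``centre + magnitude * sigma`` of its own trailing XmR baseline, so the
    scan recovers the stated magnitude by construction.
    """
    if n_months < baseline_length + 1:
        raise ValueError(f"need n_months >= {baseline_length + 1}")
    if noise_cv < 0 or base_level <= 0:
        raise ValueError("noise_cv must be >= 0 and base_level > 0")
    t = np.arange(n_months)
    values = np.empty((n_cases, n_months))
    for i in range(n_cases):
        rng = _row_rng(seed, i)
        level = base_level * rng.lognormal(mean=0.0, sigma=0.4)
        noise = 1.0 + noise_cv * rng.standard_normal(n_months)
        values[i] = np.maximum(level * (1.0 + drift) ** t * noise, 0.0)
    for shock in outlier_spec or []:
        if not baseline_length <= shock.month < n_months:
            raise ValueError(f"shock month {shock.month} outside the scored region")
        if shock.duration < 1:
            raise ValueError("shock duration must be >= 1")
        row = values[shock.case]
        for m in range(shock.month, min(shock.month + shock.duration, n_months)):
            window = row[m - baseline_length:m]
            sigma = np.abs(np.diff(window)).mean() / 1.128
            row[m] = window.mean() + shock.magnitude * sigma
    return ExpenditureMatrix(
        case_ids=[f"case{i}" for i in range(n_cases)],
        month_labels=month_labels(start, n_months),
        values=values,
        n_dropped=0,
    )
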