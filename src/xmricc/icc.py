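"""Two-way ANOVA without replication and the consistency average-measure ICC.

A complete n x k grid (cases in rows, months/items in columns) is decomposed
into row, column and residual sums of squares.  The intraclass correlation
reported here is the two-way, consistency-type, *average*-measure coefficient
ICC(C,k) = (MS_rows - MS_error) / MS_rows, numerically identical to
Cronbach's alpha; its 95% interval is the F-based (Feldt) interval.

In the monitoring application a LOW ICC is the good outcome: months that
cannot tell the hospitals apart mean every hospital fluctuates the same way
around its own control-chart centre line, i.e. expenditures are homogeneously
in control.  The companion indices read the same way: SEM rises and the
separation/strata indices fall as the panel becomes more homogeneous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .data_io import YearBlock
from .xmr import SdScoreMatrix


class DegenerateMatrixError(ValueError):
    """Raised when a grid has no usable variance decomposition."""


@dataclass
class AnovaDecomposition:
    """Sums of squares, mean squares, F ratios for a two-way layout without
    replication (rows = cases, columns = items)."""

    ss_rows: float
    ss_cols: float
    ss_error: float
    ss_total: float
    df_rows: int
    df_cols: int
    df_error: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    f_rows: float
    f_cols: float
    p_rows: float
    p_cols: float
    degenerate: bool = False

    @property
    def n_cases(self) -> int:
        return self.df_rows + 1

    @property
    def k_items(self) -> int:
        return self.df_cols + 1

    @classmethod
    def from_ss(cls, ss_rows: float, df_rows: int, ss_cols: float, df_cols: int,
                ss_error: float, df_error: int) -> "AnovaDecomposition":
        """Build a decomposition from printed SS/df entries of an ANOVA table."""
        ms_rows = ss_rows / df_rows
        ms_cols = ss_cols / df_cols
        ms_error = ss_error / df_error
        if ms_error == 0.0:
            f_rows = f_cols = p_rows = p_cols = math.nan
            degenerate = True
        else:
            f_rows = ms_rows / ms_error
            f_cols = ms_cols / ms_error
            p_rows = float(stats.f.sf(f_rows, df_rows, df_error))
            p_cols = float(stats.f.sf(f_cols, df_cols, df_error))
            degenerate = False
        return cls(
            ss_rows=ss_rows, ss_cols=ss_cols, ss_error=ss_error,
            ss_total=ss_rows + ss_cols + ss_error,
            df_rows=df_rows, df_cols=df_cols, df_error=df_error,
            ms_rows=ms_rows, ms_cols=ms_cols, ms_error=ms_error,
            f_rows=f_rows, f_cols=f_cols, p_rows=p_rows, p_cols=p_cols,
            degenerate=degenerate,
        )


@dataclass
class IccEstimate:
    """Point ICC(C,k) with its F test and 95% confidence bounds."""

    icc: float
    ci_low: float
    ci_high: float
    f_obs: float
    p: float
    n_cases: int
    k_items: int
    degenerate: bool = False


@dataclass
class DerivedIndices:
    """SEM, separation index and person-strata count derived from reliability."""

    sem: float
    g_p: float
    strata: float


@dataclass
class TrendResult:
    """Linear trend of a yearly ICC series."""

    yearly_icc: dict
    r: float
    t_stat: float
    p: float
    r_squared: float
    slope: float
    degenerate: bool = False


def two_way_anova(matrix) -> AnovaDecomposition:
    """Textbook two-way decomposition of a complete n x k numeric grid."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D grid")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least a 2 x 2 grid, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("grid contains missing cells; complete cases only")
    grand = x.mean()
    ss_rows = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_cols = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = max(ss_total - ss_rows - ss_cols, 0.0)
    return AnovaDecomposition.from_ss(ss_rows, n - 1, ss_cols, k - 1,
                                      ss_error, (n - 1) * (k - 1))


def icc_confidence_interval(icc: float, n_cases: int, k_items: int,
                            alpha: float = 0.05) -> tuple[float, float]:
    """F-based (Feldt) interval for the consistency average-measure ICC.

    With F_obs = 1/(1-ICC), df1 = n-1 and df2 = (n-1)(k-1):
    low  = 1 - 1/(F_obs / F(1-alpha/2; df1, df2)),
    high = 1 - 1/(F_obs * F(1-alpha/2; df2, df1)).
    """
    if n_cases < 2 or k_items < 2:
        raise ValueError("need n_cases >= 2 and k_items >= 2")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    f_obs = 1.0 / (1.0 - icc)
    df1, df2 = n_cases - 1, (n_cases - 1) * (k_items - 1)
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    return float(1 - 1 / fl), float(1 - 1 / fu)


def icc_from_anova(anova: AnovaDecomposition, alpha: float = 0.05) -> IccEstimate:
    """ICC(C,k) = (MS_rows - MS_error)/MS_rows with Feldt CI and F test.

    The between-case mean square carries the "true" variance of the rating
    and the residual mean square the error variance; their normalized
    difference is the consistency coefficient (== Cronbach's alpha).
    """
    n, k = anova.n_cases, anova.k_items
    if anova.ms_rows == 0.0:
        return IccEstimate(icc=math.nan, ci_low=math.nan, ci_high=math.nan,
                           f_obs=math.nan, p=math.nan, n_cases=n, k_items=k,
                           degenerate=True)
    if anova.ms_error == 0.0:
        return IccEstimate(icc=1.0, ci_low=1.0, ci_high=1.0,
                           f_obs=math.inf, p=0.0, n_cases=n, k_items=k)
    icc = (anova.ms_rows - anova.ms_error) / anova.ms_rows
    low, high = icc_confidence_interval(icc, n, k, alpha=alpha)
    return IccEstimate(icc=float(icc), ci_low=low, ci_high=high,
                       f_obs=float(anova.f_rows), p=float(anova.p_rows),
                       n_cases=n, k_items=k)


def sem(sd_x: float, r_xx: float) -> float:
    """Standard error of measurement: SEM = SD_x * sqrt(1 - r_xx)."""
    if sd_x < 0:
        raise ValueError("sd_x must be non-negative")
    if r_xx > 1:
        raise ValueError("reliability cannot exceed 1")
    return float(sd_x * math.sqrt(1.0 - r_xx))


def strata_index(r_xx: float) -> tuple[float, float]:
    """Separation index G_p = sqrt(r/(1-r)) and strata = (4*G_p + 1)/3.

    Strata below 2 (e.g. 1.67 at r = 0.5) mean the cases form essentially a
    single indistinguishable group.
    """
    if not 0 <= r_xx < 1:
        raise ValueError("reliability must lie in [0, 1)")
    g_p = math.sqrt(r_xx / (1.0 - r_xx))
    return g_p, (4.0 * g_p + 1.0) / 3.0


def derived_indices(sd_x: float, r_xx: float) -> DerivedIndices:
    """Bundle SEM and the separation/strata indices for one reliability.

    A negative reliability carries no separation information, so the
    separation indices are evaluated at 0 (one stratum); reliability 1 gives
    infinite separation.
    """
    if r_xx >= 1:
        g_p, strata = math.inf, math.inf
    else:
        g_p, strata = strata_index(max(r_xx, 0.0))
    return DerivedIndices(sem=sem(sd_x, r_xx), g_p=g_p, strata=strata)


def yearly_icc_series(scores: SdScoreMatrix, blocks: list[YearBlock],
                      use: str = "bands", alpha: float = 0.05
                      ) -> dict[int, IccEstimate]:
    """Per calendar year, run the two-way ANOVA on the n x 12 block.

    ``use`` selects the response grid: ``"bands"`` (ordinal codes treated as
    numeric, the default) or ``"sd"`` (continuous distances).
    """
    grid = scores.band_codes if use == "bands" else scores.sd_values
    if use not in ("bands", "sd"):
        raise ValueError("use must be 'bands' or 'sd'")
    out: dict[int, IccEstimate] = {}
    for block in blocks:
        sub = grid[:, list(block.columns)]
        if np.isnan(sub).any():
            raise ValueError(f"year {block.year} contains unscored (burn-in) cells")
        out[block.year] = icc_from_anova(two_way_anova(sub), alpha=alpha)
    return out


def trend_stats(yearly: Mapping[int, "IccEstimate | float"]) -> TrendResult:
    """Pearson trend of ICC against calendar year, with t test and slope."""
    years = np.array(sorted(yearly), dtype=float)
    iccs = np.array([getattr(yearly[int(y)], "icc", yearly[int(y)]) for y in years],
                    dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 yearly points for a trend")
    ydict = {int(y): float(v) for y, v in zip(years, iccs)}
    if np.allclose(iccs, iccs[0]) or np.allclose(years, years[0]):
        return TrendResult(yearly_icc=ydict, r=math.nan, t_stat=math.nan,
                           p=math.nan, r_squared=math.nan, slope=0.0,
                           degenerate=True)
    r = float(stats.pearsonr(years, iccs).statistic)
    n = len(years)
    t_stat = abs(r) * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = float(2 * stats.t.sf(t_stat, df=n - 2))
    slope = float(stats.linregress(years, iccs).slope)
    return TrendResult(yearly_icc=ydict, r=r, t_stat=float(t_stat), p=p,
                       r_squared=r * r, slope=slope)


def chisq_table(observed) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c contingency table (no continuity
    correction); expected counts from the margins."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p)
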