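"""Cross-trial statistics: correlations, exponential fits, summaries.

Speed-accuracy tradeoffs are quantified with Pearson and Spearman
correlations between completion time and error; age trends with the same
correlations against age; dispersion with mean, sample SD, a normal 95%
CI and the coefficient of variation; and the time-error point cloud is
summarized with a log-linear exponential best fit y = a * exp(b x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ParameterError


@dataclass(frozen=True)
class PairedSample:
    x: np.ndarray
    y: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if len(self.x) != len(self.y):
            raise ParameterError("x and y must have equal length")


@dataclass(frozen=True)
class CorrelationResult:
    pearson_r: float
    spearman_rho: float
    p_value: float              # two-sided, for the Pearson coefficient
    n: int


@dataclass(frozen=True)
class ExpFit:
    a: float
    b: float
    rss: float                  # residual sum of squares on the original scale


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    ci95: tuple[float, float]
    cv: float | None            # undefined (None) when the mean is ~0
    n: int


def correlate(sample: PairedSample) -> CorrelationResult:
    """Pearson on raw values, Spearman on average ranks."""
    x, y = sample.x, sample.y
    if len(x) < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if float(np.std(x)) < 1e-15 or float(np.std(y)) < 1e-15:
        raise ParameterError("correlation undefined for zero-variance input")
    pr = sps.pearsonr(x, y)
    rho = sps.spearmanr(x, y).statistic
    return CorrelationResult(float(pr.statistic), float(rho),
                             float(pr.pvalue), len(x))


def fit_exponential(sample: PairedSample) -> ExpFit:
    """Log-linear least squares for y = a * exp(b x) (requires y > 0)."""
    x, y = sample.x, sample.y
    if len(x) < 3:
        raise InsufficientDataError("exponential fit needs n >= 3")
    if np.any(y <= 0):
        raise ParameterError("exponential fit requires positive y")
    slope, intercept = np.polyfit(x, np.log(y), 1)
    a, b = float(np.exp(intercept)), float(slope)
    rss = float(np.sum((y - a * np.exp(b * x)) ** 2))
    return ExpFit(a, b, rss)


def summarize(values) -> SummaryStats:
    """Mean, sample SD (n-1), normal 95% CI, CV."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise InsufficientDataError("summarize needs n >= 1")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    half = 1.96 * sd / np.sqrt(len(v))
    cv = None if abs(mean) < 1e-12 else sd / mean
    return SummaryStats(mean, sd, (mean - half, mean + half), cv, len(v))


def speed_accuracy_report(metrics: pd.DataFrame,
                          group_by: str = "game") -> pd.DataFrame:
    """Correlation + exponential-fit table over per-trial metrics.

    ``metrics`` needs columns ``game``, ``completion_s``, ``error`` and
    (for the age analysis) ``age_years``.  With ``group_by='game'`` each
    game contributes a speed-vs-error row; with ``group_by='age'`` each
    game contributes an age-vs-error row.  Groups with fewer than 3
    usable trials yield a warning row with NaN statistics.
    """
    if group_by not in ("game", "age"):
        raise ParameterError("group_by must be 'game' or 'age'")
    rows = []
    for game, df in metrics.groupby("game", sort=True):
        if group_by == "game":
            df = df.dropna(subset=["completion_s", "error"])
            x, y = df["completion_s"].to_numpy(), df["error"].to_numpy()
            pair_name = "completion_s~error"
        else:
            df = df.dropna(subset=["age_years", "error"])
            x, y = df["age_years"].to_numpy(), df["error"].to_numpy()
            pair_name = "age_years~error"
        row = {"game": game, "pair": pair_name, "n": len(x),
               "pearson_r": np.nan, "spearman_rho": np.nan,
               "p_value": np.nan, "exp_a": np.nan, "exp_b": np.nan,
               "warning": ""}
        if len(x) < 3:
            row["warning"] = "too few trials for correlation"
        elif np.std(x) < 1e-15 or np.std(y) < 1e-15:
            row["warning"] = "zero variance"
        else:
            c = correlate(PairedSample(x, y))
            row.update(pearson_r=c.pearson_r, spearman_rho=c.spearman_rho,
                       p_value=c.p_value)
            if np.all(y > 0):
                fit = fit_exponential(PairedSample(x, y))
                row.update(exp_a=fit.a, exp_b=fit.b)
        rows.append(row)
    return pd.DataFrame(rows)
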