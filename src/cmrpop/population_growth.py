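"""Breeding-success statistics and census-based population growth.

The stochastic growth rate follows the log-growth regression for possibly
unequal census intervals: for consecutive census pairs separated by ``tau``
years, regress ``ln(N_next/N) / sqrt(tau)`` on ``sqrt(tau)`` without
intercept; the slope estimates the mean log growth ``mu`` and the residual
mean square the environmental variance ``sigma^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ProductivityRecord",
    "CensusSeries",
    "GrowthEstimate",
    "SummaryTestResult",
    "breeding_success",
    "summary_t_test",
    "annual_lambda",
    "dennis_stochastic_lambda",
    "geometric_mean_lambda",
    "combine_series",
]


@dataclass(frozen=True)
class ProductivityRecord:
    year: int
    nests: int
    fledglings: int

    def __post_init__(self) -> None:
        if self.nests < 0 or self.fledglings < 0:
            raise ValueError("counts must be non-negative")

    @property
    def breeding_success(self) -> float:
        return breeding_success(self.nests, self.fledglings)


def breeding_success(nests: int, fledglings: int) -> float:
    """Fledglings per nest; may exceed 1 for multi-chick broods."""
    if nests <= 0:
        raise ValueError("breeding success undefined for zero nests")
    return fledglings / nests


@dataclass(frozen=True)
class SummaryTestResult:
    t: float
    df: int
    p: float


def summary_t_test(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> SummaryTestResult:
    """Two-sample t test from summary means and standard errors.

    ``t = |mean2 - mean1| / sqrt(se1^2 + se2^2)`` with pooled
    ``df = n1 + n2 - 2`` and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per sample")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    t_stat = abs(mean2 - mean1) / float(np.hypot(se1, se2))
    df = n1 + n2 - 2
    p = 2.0 * float(stats.t.sf(t_stat, df))
    return SummaryTestResult(float(t_stat), df, p)


@dataclass(frozen=True)
class CensusSeries:
    """Annual nest counts for one region; gap years simply absent."""

    region: str
    counts: Mapping[int, float]

    def __post_init__(self) -> None:
        years = list(self.counts)
        if years != sorted(set(years)):
            raise ValueError("census years must be strictly increasing")
        if any(v <= 0 for v in self.counts.values()):
            raise ValueError("census counts must be positive where present")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.counts)

    @classmethod
    def from_file(cls, path: str | Path, region: str | None = None
                  ) -> "CensusSeries":
        path = Path(path)
        table: dict[int, float] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", " ").split()
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'year count', got {line!r}"
                    )
                table[int(parts[0])] = float(parts[1])
        return cls(region or path.stem, dict(sorted(table.items())))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for year, count in self.counts.items():
                fh.write(f"{year}\t{count:g}\n")


def combine_series(
    series: Sequence[CensusSeries],
    region: str = "combined",
    require_all: bool = True,
) -> CensusSeries:
    """Year-wise sum of regional series.

    With ``require_all`` (default) a year missing from any region becomes a
    gap in the combined series; otherwise available regions are summed.
    """
    all_years = sorted({y for s in series for y in s.years})
    counts: dict[int, float] = {}
    for year in all_years:
        present = [s.counts[year] for s in series if year in s.counts]
        if require_all and len(present) != len(series):
            continue
        counts[year] = float(sum(present))
    return CensusSeries(region, counts)


def annual_lambda(series: CensusSeries) -> dict[int, float]:
    """``lambda_t = N_{t+1}/N_t`` for consecutive-year pairs only."""
    if len(series.years) < 2:
        raise ValueError("need at least two census years")
    out: dict[int, float] = {}
    for y0, y1 in zip(series.years, series.years[1:]):
        if y1 == y0 + 1:
            out[y0] = series.counts[y1] / series.counts[y0]
    return out


@dataclass(frozen=True)
class GrowthEstimate:
    region: str
    mu_hat: float
    sigma2_hat: float
    lambda_s: float
    ci: tuple[float, float]
    q: int
    alpha: float

    @property
    def decline_flag(self) -> bool:
        """True when the CI lower limit is below 1 (long-term decline
        cannot be ruled out); never a point conclusion."""
        return self.ci[0] < 1.0


def dennis_stochastic_lambda(
    series: CensusSeries, alpha: float = 0.05
) -> GrowthEstimate:
    """Stochastic growth rate with CI from the log-growth regression.

    Handles unequal census intervals (gaps); ``lambda_s = exp(mu_hat)`` (the
    median-growth convention) with a t-based confidence interval on ``mu``.
    """
    years = np.asarray(series.years, dtype=float)
    counts = np.asarray([series.counts[y] for y in series.years], dtype=float)
    if years.size < 3:
        raise ValueError("need at least three census points (two transitions)")
    tau = np.diff(years)
    x = np.sqrt(tau)
    y = np.log(counts[1:] / counts[:-1]) / x
    q = x.size
    sxx = float(np.sum(x * x))
    mu = float(np.sum(x * y) / sxx)
    resid = y - mu * x
    sigma2 = float(np.sum(resid ** 2) / (q - 1))
    se = np.sqrt(sigma2 / sxx)
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, q - 1))
    lo, hi = np.exp(mu - tq * se), np.exp(mu + tq * se)
    return GrowthEstimate(
        series.region, mu, sigma2, float(np.exp(mu)), (float(lo), float(hi)),
        q, alpha,
    )


def geometric_mean_lambda(lambdas: Sequence[float]) -> float:
    """``exp(mean(log(lambda)))``; all rates must be positive."""
    arr = np.asarray(list(lambdas), dtype=float)
    if arr.size == 0:
        raise ValueError("empty growth-rate sequence")
    if (arr <= 0).any():
        raise ValueError("growth rates must be positive")
    return float(np.exp(np.mean(np.log(arr))))
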