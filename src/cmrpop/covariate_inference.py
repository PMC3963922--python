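"""Covariate preparation and ANODEV testing.

ANODEV compares three nested fits -- constant, covariate, fully
time-dependent -- and asks whether the deviance the covariate captures is a
significant share of the total temporal deviance:

    F = [(Dev_cst - Dev_cov)/(np_cov - np_cst)]
        / [(Dev_cov - Dev_t)/(np_t - np_cov)]

with r^2 = (Dev_cst - Dev_cov)/(Dev_cst - Dev_t) the explained fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from cmrpop.cjs_model import Formula, Segment, Term, parse_formula

__all__ = [
    "CovariateSeries",
    "AnodevResult",
    "anodev",
    "anodev_references",
    "standardize",
    "fill_covariate_gaps",
]


@dataclass(frozen=True)
class CovariateSeries:
    """Named annual covariate series (FISH, MAR, NAO, ...)."""

    name: str
    years: tuple[int, ...]
    values: np.ndarray
    standardized: bool = False
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.years) != len(self.values):
            raise ValueError("years and values differ in length")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )

    @classmethod
    def from_mapping(cls, name: str, table: Mapping[int, float]
                     ) -> "CovariateSeries":
        years = tuple(sorted(table))
        return cls(name, years, np.array([table[y] for y in years], float))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None
                  ) -> "CovariateSeries":
        """Read a 2-column ``year value`` text file (comma or whitespace)."""
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
                        f"{path}:{lineno}: expected 'year value', got {line!r}"
                    )
                try:
                    table[int(parts[0])] = float(parts[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
        return cls.from_mapping(name or path.stem, table)

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.years, map(float, self.values)))


def standardize(series: CovariateSeries) -> CovariateSeries:
    """Center and scale to zero mean / unit population sd (denominator n)."""
    if len(series.values) < 2:
        raise ValueError("need at least two values to standardize")
    sd = float(np.std(series.values))
    if sd == 0.0:
        raise ValueError(f"covariate {series.name!r} is constant")
    z = (series.values - series.values.mean()) / sd
    raw = series.raw_values if series.raw_values is not None else series.values
    return CovariateSeries(series.name, series.years, z, True, raw)


def fill_covariate_gaps(
    series: CovariateSeries, years: Sequence[int] | None = None
) -> CovariateSeries:
    """Fill interior missing years by monotone piecewise cubic Hermite
    (PCHIP) interpolation; observed values are kept untouched.

    ``years`` defaults to the full consecutive range spanned by the observed
    years.  Requesting years outside that range is an error (no
    extrapolation).
    """
    if len(series.years) < 2:
        raise ValueError("need at least two observed values")
    target = (
        tuple(range(series.years[0], series.years[-1] + 1))
        if years is None
        else tuple(sorted(int(y) for y in years))
    )
    if target[0] < series.years[0] or target[-1] > series.years[-1]:
        raise ValueError(
            "gap at series boundary: interpolation only, no extrapolation"
        )
    if target == series.years:
        return series
    interp = PchipInterpolator(np.asarray(series.years, float), series.values)
    observed = series.as_dict()
    filled = np.array(
        [observed.get(y, float(interp(y))) for y in target], dtype=float
    )
    return CovariateSeries(series.name, target, filled, series.standardized)


@dataclass(frozen=True)
class AnodevResult:
    F: float
    df1: int
    df2: int
    p: float
    r2: float


def anodev(
    dev_cst: float,
    np_cst: int,
    dev_cov: float,
    np_cov: int,
    dev_t: float,
    np_t: int,
) -> AnodevResult:
    """Analysis of deviance for one covariate between nested reference fits.

    The three deviances must come from the same dataset and share the
    resighting structure; ``np_*`` are the (printed or nominal) parameter
    counts whose differences give the F degrees of freedom.
    """
    if not (np_cst < np_cov < np_t):
        raise ValueError(
            f"parameter counts must nest: np_cst={np_cst} < np_cov={np_cov} "
            f"< np_t={np_t}"
        )
    if dev_cst < dev_t:
        raise ValueError(
            "dev_cst < dev_t: constant and time reference models inverted"
        )
    df1 = np_cov - np_cst
    df2 = np_t - np_cov
    num = dev_cst - dev_cov
    den = dev_cov - dev_t
    if num < 0:
        warnings.warn(
            "covariate model fit worse than constant model; clipping "
            "explained deviance to 0 (optimizer noise)",
            RuntimeWarning,
        )
        num = 0.0
    if den < 0:
        warnings.warn(
            "covariate model fit better than time model; clipping residual "
            "deviance to 0 (optimizer noise)",
            RuntimeWarning,
        )
        den = 0.0
    total = dev_cst - dev_t
    r2 = num / total if total > 0 else 0.0
    if den == 0.0:
        f_stat = np.inf if num > 0 else 0.0
    else:
        f_stat = (num / df1) / (den / df2)
    p = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return AnodevResult(float(f_stat), df1, df2, p, float(r2))


def _strip_or_replace(formula: Formula, cov: str, with_time: bool) -> Formula:
    segments = []
    for seg in formula.segments:
        terms: list[Term] = []
        for term in seg.terms:
            if cov not in term.factors:
                terms.append(term)
                continue
            if with_time:
                kept = tuple(("t" if f == cov else f) for f in term.factors)
            else:
                kept = tuple(f for f in term.factors if f != cov)
            # collapse repeated factors (e.g. t.t after substitution)
            dedup: list[str] = []
            for f in kept:
                if f not in dedup:
                    dedup.append(f)
            if dedup:
                terms.append(Term(tuple(dedup)))
        if not terms:
            terms = [Term(("age",))]
        # drop terms that became duplicates of an existing pure-age term
        uniq: list[Term] = []
        for term in terms:
            if term not in uniq:
                uniq.append(term)
        segments.append(Segment(seg.classes, tuple(uniq)))
    text = "/".join(
        _render_segment(seg) for seg in segments
    )
    return parse_formula(text)


def _render_segment(seg: Segment) -> str:
    parts = []
    for term in seg.terms:
        bits = []
        for f in term.factors:
            if f == "age":
                bits.append(
                    "a(" + ",".join(str(c) for c in seg.classes) + ")"
                )
            else:
                bits.append(f)
        parts.append(".".join(bits))
    return "+".join(parts)


def anodev_references(formula: Formula | str, cov: str
                      ) -> tuple[Formula, Formula]:
    """Derive the (constant, time) reference formulas for a covariate model.

    The constant reference drops the covariate's effect back to a constant
    in the affected age class(es); the time reference substitutes a time
    effect in the same structural position -- interactive covariate becomes
    interactive time, an additive shared covariate becomes additive time.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    if cov not in formula.covariates:
        raise ValueError(f"covariate {cov!r} not present in {formula.text!r}")
    constant = _strip_or_replace(formula, cov, with_time=False)
    timeref = _strip_or_replace(formula, cov, with_time=True)
    return constant, timeref
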