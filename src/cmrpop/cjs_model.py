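"""Constrained Cormack-Jolly-Seber models: grammar, likelihood, fitting, AICc.

Model structure is written in a compact grammar::

    a(1,2,>=3).t        one parameter per (age class, time)
    a(1,>=2)+t          age-class intercepts plus an additive time effect
    a(1).t/a(>=2)       '/' separates independent per-age-class structures
    a(1).FISH/a(>=2)    interaction with a named annual covariate
    a(1).col.t          crossed with a colony (group) effect

Tokens: ``a(...)`` age-class lists (1-based years since marking, the last
class open-ended with ``>=``), ``t`` time, ``col`` group, and uppercase
covariate names.  ``.`` denotes interaction, ``+`` an additive effect and
``/`` independence between age classes.  Within a ``.``-product that
contains the age factor, a covariate contributes an intercept *and* a slope
per categorical level combination; a bare ``+COV`` term contributes a single
shared slope.

Parameters live on the logit scale.  The likelihood is the cohort-structured
m-array multinomial: a bird released at occasion ``i`` is first re-seen at
``j`` with probability ``prod_{k=i..j-2} phi_k (1-p_{k+1}) * phi_{j-1} p_j``,
with phi and p indexed by age (= occasion - cohort) and time.  Reported
deviance is relative to the row-wise saturated multinomial, so it is
non-negative and comparable across models of one dataset.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from cmrpop.encounter_data import MArray

__all__ = [
    "AgeClass",
    "Term",
    "Segment",
    "Formula",
    "ModelSpec",
    "DesignStructure",
    "FitOptions",
    "FitResult",
    "parse_formula",
    "parse_model_spec",
    "build_design",
    "cjs_neg_log_likelihood",
    "fit_cjs",
    "compute_aicc",
    "count_estimable",
    "model_selection_table",
]

_RESERVED = {"t", "col", "a"}


class FormulaSyntaxError(ValueError):
    """Raised on malformed model-grammar strings."""


@dataclass(frozen=True)
class AgeClass:
    """Contiguous age class in years since marking; ``hi=None`` is open."""

    lo: int
    hi: int | None

    def contains(self, age: int) -> bool:
        return age >= self.lo and (self.hi is None or age <= self.hi)

    def __str__(self) -> str:
        if self.hi is None:
            return f">={self.lo}"
        if self.hi == self.lo:
            return str(self.lo)
        return f"{self.lo}-{self.hi}"


@dataclass(frozen=True)
class Term:
    """A '.'-product of factors: 'age', 't', 'col' and/or covariate names."""

    factors: tuple[str, ...]

    @property
    def categorical(self) -> tuple[str, ...]:
        return tuple(f for f in self.factors if f in ("age", "t", "col"))

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(f for f in self.factors if f not in ("age", "t", "col"))

    def __str__(self) -> str:
        return ".".join(self.factors)


@dataclass(frozen=True)
class Segment:
    """Age classes plus the additive terms that apply to them."""

    classes: tuple[AgeClass, ...]
    terms: tuple[Term, ...]


@dataclass(frozen=True)
class Formula:
    """Parsed model formula for one parameter type (survival or resight)."""

    segments: tuple[Segment, ...]
    text: str

    @property
    def covariates(self) -> tuple[str, ...]:
        names: dict[str, None] = {}
        for seg in self.segments:
            for term in seg.terms:
                for cov in term.covariates:
                    names.setdefault(cov, None)
        return tuple(names)

    def segment_for_age(self, age: int) -> tuple[int, int]:
        """Return (segment index, class index within segment) for an age."""
        for si, seg in enumerate(self.segments):
            for ci, cls in enumerate(seg.classes):
                if cls.contains(age):
                    return si, ci
        raise ValueError(
            f"age {age} not covered by formula {self.text!r}; "
            "age-class lists must cover all realized ages"
        )

    def __str__(self) -> str:
        return self.text


@dataclass(frozen=True)
class ModelSpec:
    """Survival and resighting formulas making up one candidate model."""

    survival: Formula
    resight: Formula
    name: str | None = None

    def label(self) -> str:
        return self.name or f"phi({self.survival}) p({self.resight})"


def _parse_age_classes(body: str, text: str) -> tuple[AgeClass, ...]:
    items = [s.strip() for s in body.split(",") if s.strip()]
    if not items:
        raise FormulaSyntaxError(f"empty age-class list in {text!r}")
    classes: list[AgeClass] = []
    for i, item in enumerate(items):
        if item.startswith(">="):
            if i != len(items) - 1:
                raise FormulaSyntaxError(
                    f"open class must be last in {text!r}"
                )
            classes.append(AgeClass(int(item[2:]), None))
        else:
            if not item.isdigit():
                raise FormulaSyntaxError(
                    f"illegal age-class token {item!r} in {text!r}"
                )
            classes.append(AgeClass(int(item), int(item)))
    for prev, cur in zip(classes, classes[1:]):
        if cur.lo != (prev.hi or 0) + 1:
            raise FormulaSyntaxError(
                f"age classes must be contiguous and ascending in {text!r}"
            )
    return tuple(classes)


_TOKEN = re.compile(r"a\([^)]*\)|[A-Za-z_][A-Za-z0-9_]*|[.+]|1")


def _parse_segment(segtext: str, text: str) -> Segment:
    segtext = segtext.strip()
    if not segtext:
        raise FormulaSyntaxError(f"empty '/' segment in {text!r}")
    pos = 0
    tokens: list[str] = []
    while pos < len(segtext):
        if segtext[pos].isspace():
            pos += 1
            continue
        match = _TOKEN.match(segtext, pos)
        if match is None:
            raise FormulaSyntaxError(
                f"syntax error at position {pos} in {text!r}"
            )
        tokens.append(match.group())
        pos = match.end()

    classes: tuple[AgeClass, ...] | None = None
    # split the token stream on '+' into '.'-products
    products: list[list[str]] = [[]]
    expect_operand = True
    for tok in tokens:
        if tok in (".", "+"):
            if expect_operand:
                raise FormulaSyntaxError(f"dangling operator in {text!r}")
            if tok == "+":
                products.append([])
            expect_operand = True
            continue
        if not expect_operand:
            raise FormulaSyntaxError(f"missing operator in {text!r}")
        expect_operand = False
        if tok.startswith("a("):
            if classes is not None:
                raise FormulaSyntaxError(f"duplicate a() in segment of {text!r}")
            classes = _parse_age_classes(tok[2:-1], text)
            products[-1].append("age")
        elif tok in ("t", "col"):
            products[-1].append(tok)
        elif tok == "1":
            pass  # bare intercept; the implicit age factor supplies it
        else:
            products[-1].append(tok)  # covariate name, validated at design time
    if expect_operand and tokens:
        raise FormulaSyntaxError(f"dangling operator in {text!r}")

    if classes is None:
        classes = (AgeClass(1, None),)
        # fold the implicit single age class into the first product so that
        # bare "t" means one parameter per occasion and "1" a single intercept
        products[0].insert(0, "age")
    terms = tuple(Term(tuple(p)) for p in products if p)
    if not terms:
        terms = (Term(("age",)),)
    return Segment(classes, terms)


def parse_formula(text: str) -> Formula:
    """Parse one grammar string into a :class:`Formula`.

    >>> parse_formula("a(1).t/a(>=2)").segments[0].terms
    (Term(factors=('age', 't')),)
    """
    if not text or not text.strip():
        raise FormulaSyntaxError("empty formula")
    norm = text.replace("≥", ">=").replace(" ", "")
    segments = tuple(_parse_segment(s, text) for s in norm.split("/"))
    lows = []
    for seg in segments:
        lows.extend((c.lo, c.hi) for c in seg.classes)
    lows.sort(key=lambda c: c[0])
    if lows[0][0] != 1:
        raise FormulaSyntaxError(f"age classes must start at 1 in {text!r}")
    for (_, hi), (lo2, _) in zip(lows, lows[1:]):
        if hi is None or lo2 != hi + 1:
            raise FormulaSyntaxError(
                f"age classes across segments must be disjoint and "
                f"contiguous in {text!r}"
            )
    return Formula(segments, norm)


def parse_model_spec(
    survival: str, resight: str = "t", name: str | None = None
) -> ModelSpec:
    """Build a :class:`ModelSpec` from survival and resight grammar strings."""
    return ModelSpec(parse_formula(survival), parse_formula(resight), name)


# ---------------------------------------------------------------------------
# Design structure
# ---------------------------------------------------------------------------


@dataclass
class ParamDesign:
    """Design for one parameter type: cell index map and design matrix."""

    formula: Formula
    cells: list[tuple[str, int, int, int]]  # (group, seg, class, time)
    cell_index: dict[tuple[str, int, int, int], int]
    X: np.ndarray
    column_labels: list[str]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


@dataclass
class DesignStructure:
    """Compiled linear-predictor structure for a model on one dataset."""

    spec: ModelSpec
    occasions: tuple[int, ...]
    groups: tuple[str, ...]
    phi: ParamDesign
    p: ParamDesign
    covariates: dict[str, Mapping[int, float]] = field(default_factory=dict)

    @property
    def parameter_count_nominal(self) -> int:
        return self.phi.n_params + self.p.n_params

    def split(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = self.phi.n_params
        return beta[:k], beta[k:]

    def cell_values(self, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Real-scale phi and p values per realized cell."""
        b_phi, b_p = self.split(np.asarray(beta, dtype=float))
        return expit(self.phi.X @ b_phi), expit(self.p.X @ b_p)


def _standardized_lookup(
    name: str, series, occasions: tuple[int, ...]
) -> Mapping[int, float]:
    # accept CovariateSeries or plain year->value mappings
    from cmrpop.covariate_inference import CovariateSeries, standardize

    if isinstance(series, CovariateSeries):
        cov = series if series.standardized else standardize(series)
        return dict(zip(cov.years, cov.values))
    if isinstance(series, Mapping):
        cov = standardize(CovariateSeries(name, tuple(series), np.asarray(
            [series[y] for y in series], dtype=float)))
        return dict(zip(cov.years, cov.values))
    raise TypeError(f"covariate {name!r}: expected CovariateSeries or mapping")


def _realized_cells(
    formula: Formula,
    occasions: tuple[int, ...],
    groups: tuple[str, ...],
    cohorts: Mapping[str, Sequence[int]],
    kind: str,
) -> list[tuple[str, int, int, int]]:
    t = len(occasions)
    cells: dict[tuple[str, int, int, int], None] = {}
    for g in groups:
        for c in cohorts[g]:
            if kind == "phi":
                # intervals k = c .. T-2; age during interval k is k - c + 1
                for k in range(c, t - 1):
                    si, ci = formula.segment_for_age(k - c + 1)
                    cells.setdefault((g, si, ci, k), None)
            else:
                # resight occasions j = c+1 .. T-1; age at j is j - c
                for j in range(c + 1, t):
                    si, ci = formula.segment_for_age(j - c)
                    cells.setdefault((g, si, ci, j), None)
    return sorted(cells)


def _build_param_design(
    formula: Formula,
    occasions: tuple[int, ...],
    groups: tuple[str, ...],
    cohorts: Mapping[str, Sequence[int]],
    covariates: Mapping[str, Mapping[int, float]],
    kind: str,
) -> ParamDesign:
    cells = _realized_cells(formula, occasions, groups, cohorts, kind)
    cell_index = {cell: i for i, cell in enumerate(cells)}
    columns: list[np.ndarray] = []
    labels: list[str] = []

    for si, seg in enumerate(formula.segments):
        seg_cells = [
            (idx, cell) for idx, cell in enumerate(cells) if cell[1] == si
        ]
        for term in seg.terms:
            cats = term.categorical
            covs = term.covariates
            for cov in covs:
                if cov not in covariates:
                    raise ValueError(
                        f"unknown covariate {cov!r} in formula "
                        f"{formula.text!r}; bind it via the covariates "
                        "argument"
                    )

            def combo(cell: tuple[str, int, int, int]) -> tuple:
                g, _, ci, time = cell
                key = []
                if "age" in cats:
                    key.append(ci)
                if "col" in cats:
                    key.append(g)
                if "t" in cats:
                    key.append(time)
                return tuple(key)

            levels = sorted({combo(cell) for _, cell in seg_cells})

            def cov_value(cell: tuple[str, int, int, int]) -> float:
                val = 1.0
                year = occasions[cell[3]]
                for cov in covs:
                    table = covariates[cov]
                    if year not in table:
                        raise ValueError(
                            f"covariate {cov!r} has no value for year {year}; "
                            "use fill_covariate_gaps first"
                        )
                    val *= table[year]
                return val

            if covs and "age" in cats:
                # intercept plus slope per categorical level combination
                kinds = ("icept", "slope")
            elif covs:
                kinds = ("slope",)
            else:
                kinds = ("icept",)

            for what in kinds:
                use_levels = levels
                if what == "icept" and "age" not in cats:
                    use_levels = levels[1:]  # reference coding
                for lev in use_levels:
                    colvec = np.zeros(len(cells))
                    for idx, cell in seg_cells:
                        if combo(cell) == lev:
                            colvec[idx] = cov_value(cell) if what == "slope" else 1.0
                    if not colvec.any():
                        continue
                    labels.append(
                        f"{kind}:s{si}:{term}:{what}:" + ",".join(map(str, lev))
                    )
                    columns.append(colvec)

    if not columns:
        raise ValueError(f"formula {formula.text!r} produced no parameters")
    X = np.column_stack(columns)
    return ParamDesign(formula, cells, cell_index, X, labels)


def build_design(
    spec: ModelSpec,
    occasions: Sequence[int],
    groups: Sequence[str],
    covariates: Mapping[str, object] | None = None,
    *,
    cohorts: Mapping[str, Sequence[int]] | None = None,
) -> DesignStructure:
    """Compile a model spec into per-cell logit-scale design matrices.

    ``cohorts`` maps each group to the 0-based release occasions realized in
    the data; by default every occasion but the last is assumed to hold a
    cohort.  Covariates are standardized (zero mean, unit population sd)
    before entering the design.
    """
    occasions = tuple(int(y) for y in occasions)
    groups = tuple(groups)
    if cohorts is None:
        cohorts = {g: list(range(len(occasions) - 1)) for g in groups}
    bound = {
        name: _standardized_lookup(name, series, occasions)
        for name, series in (covariates or {}).items()
    }
    phi = _build_param_design(
        spec.survival, occasions, groups, cohorts, bound, "phi"
    )
    p = _build_param_design(spec.resight, occasions, groups, cohorts, bound, "p")
    return DesignStructure(spec, occasions, groups, phi, p, bound)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


@dataclass
class _LikelihoodData:
    """Padded index arrays mapping m-array rows onto design cells."""

    phi_idx: np.ndarray  # (rows, steps) indices into phi cell vector
    p_idx: np.ndarray  # (rows, steps) indices into p cell vector
    mask: np.ndarray  # (rows, steps) step validity
    m: np.ndarray  # (rows, steps) first-re-encounter counts
    never: np.ndarray  # (rows,)
    released: np.ndarray  # (rows,)
    saturated_nll2: float


def _prepare(design: DesignStructure, marray: MArray) -> _LikelihoodData:
    t = len(design.occasions)
    rows = marray.rows
    max_steps = max((t - 1 - r.release) for r in rows) if rows else 0
    n = len(rows)
    phi_idx = np.zeros((n, max_steps), dtype=np.int64)
    p_idx = np.zeros((n, max_steps), dtype=np.int64)
    mask = np.zeros((n, max_steps), dtype=bool)
    m = np.zeros((n, max_steps), dtype=float)
    never = np.array([r.never for r in rows], dtype=float)
    released = np.array([r.released for r in rows], dtype=float)

    sphi = design.spec.survival
    sp = design.spec.resight
    for ri, row in enumerate(rows):
        g, c, rel = row.group, row.cohort, row.release
        for s in range(t - 1 - rel):
            k = rel + s  # interval k -> k+1, detection occasion k+1
            psi, pci = sphi.segment_for_age(k - c + 1)
            qsi, qci = sp.segment_for_age(k + 1 - c)
            phi_idx[ri, s] = design.phi.cell_index[(g, psi, pci, k)]
            p_idx[ri, s] = design.p.cell_index[(g, qsi, qci, k + 1)]
            mask[ri, s] = True
            m[ri, s] = row.m[k + 1]

    # saturated multinomial reference: cell MLEs are observed proportions
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_m = np.where(m > 0, m / released[:, None], 1.0)
        frac_n = np.where(never > 0, never / released, 1.0)
    sat = -2.0 * (np.sum(m * np.log(frac_m)) + np.sum(never * np.log(frac_n)))
    return _LikelihoodData(phi_idx, p_idx, mask, m, never, released, float(sat))


_TINY = 1e-300


def _nll2_from_cells(
    data: _LikelihoodData, phi_cells: np.ndarray, p_cells: np.ndarray
) -> float:
    phi = phi_cells[data.phi_idx]
    p = p_cells[data.p_idx]
    a = np.where(data.mask, phi * (1.0 - p), 1.0)  # survive, not seen
    b = phi * p  # survive, first seen here
    lead = np.cumprod(a, axis=1) / a  # prod of A over earlier steps
    lead[:, 0] = 1.0
    prob = np.where(data.mask, lead * b, 0.0)
    chi = 1.0 - prob.sum(axis=1)
    ll = np.sum(data.m * np.log(np.maximum(prob, _TINY)))
    ll += np.sum(data.never * np.log(np.maximum(chi, _TINY)))
    return -2.0 * ll


def _row_probabilities(
    design: DesignStructure, beta: np.ndarray, marray: MArray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-release-row first-re-encounter cell probabilities and chi."""
    data = _prepare(design, marray)
    phi_cells, p_cells = design.cell_values(beta)
    phi = phi_cells[data.phi_idx]
    p = p_cells[data.p_idx]
    a = np.where(data.mask, phi * (1.0 - p), 1.0)
    b = phi * p
    lead = np.cumprod(a, axis=1) / a
    lead[:, 0] = 1.0
    prob = np.where(data.mask, lead * b, 0.0)
    chi = 1.0 - prob.sum(axis=1)
    return prob, chi, data.mask


def cjs_neg_log_likelihood(
    design: DesignStructure, beta: np.ndarray, marray: MArray
) -> float:
    """-2 log multinomial likelihood (kernel, constants omitted)."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (design.parameter_count_nominal,):
        raise ValueError(
            f"beta length {beta.shape} != nominal parameter count "
            f"{design.parameter_count_nominal}"
        )
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite linear predictor coefficients")
    data = _prepare(design, marray)
    phi_cells, p_cells = design.cell_values(beta)
    return _nll2_from_cells(data, phi_cells, p_cells)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    n_starts: int = 5
    seed: int = 0
    gtol: float = 1e-8
    maxiter: int = 2000
    compute_hessian: bool = True
    hessian_step: float = 1e-3
    rank_rtol: float = 1e-6


@dataclass
class FitResult:
    """Maximum-likelihood fit of one constrained CJS model."""

    spec: ModelSpec
    design: DesignStructure
    beta: np.ndarray
    nll2: float
    deviance: float
    np_nominal: int
    np_estimable: int
    n_eff: int
    aicc: float
    converged: bool
    vcov: np.ndarray | None = None
    hessian: np.ndarray | None = None

    @property
    def name(self) -> str:
        return self.spec.label()

    def real_scale(self, kind: str = "phi", z: float = 1.959963984540054
                   ) -> pd.DataFrame:
        """Back-transformed estimates per cell with Wald CIs inside (0, 1)."""
        pdsg = self.design.phi if kind == "phi" else self.design.p
        b_phi, b_p = self.design.split(self.beta)
        beta_k = b_phi if kind == "phi" else b_p
        eta = pdsg.X @ beta_k
        if self.vcov is not None:
            off = 0 if kind == "phi" else self.design.phi.n_params
            k = pdsg.n_params
            sub = self.vcov[off:off + k, off:off + k]
            se = np.sqrt(np.maximum(np.einsum(
                "ij,jk,ik->i", pdsg.X, sub, pdsg.X), 0.0))
        else:
            se = np.full(eta.shape, np.nan)
        rows = []
        for (g, si, ci, time), e, s in zip(pdsg.cells, eta, se):
            cls = pdsg.formula.segments[si].classes[ci]
            rows.append({
                "group": g,
                "age_class": str(cls),
                "age_lo": cls.lo,
                "year": self.design.occasions[time],
                "estimate": float(expit(e)),
                "ci_lo": float(expit(e - z * s)) if np.isfinite(s) else np.nan,
                "ci_hi": float(expit(e + z * s)) if np.isfinite(s) else np.nan,
            })
        return pd.DataFrame(rows)

    def mean_estimate(self, kind: str, age_lo: int) -> float:
        """Unweighted mean of real-scale cell estimates for one age class."""
        df = self.real_scale(kind)
        sel = df[df.age_lo == age_lo]
        if sel.empty:
            raise ValueError(f"no {kind} cells with age class starting {age_lo}")
        return float(sel.estimate.mean())


def compute_aicc(dev: float, n_params: int, n_eff: int) -> float:
    """Small-sample AIC: ``Dev + 2K + 2K(K+1)/(n_eff - K - 1)``."""
    if n_eff <= n_params + 1:
        raise ValueError(
            f"AICc undefined: n_eff={n_eff} <= n_params+1={n_params + 1}"
        )
    return dev + 2 * n_params + 2 * n_params * (n_params + 1) / (
        n_eff - n_params - 1
    )


def _fd_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray,
                step: float) -> np.ndarray:
    """Central finite-difference Hessian."""
    k = x.size
    h = step * (1.0 + np.abs(x))
    hess = np.empty((k, k))
    f0 = fun(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        hess[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                4.0 * h[i] * h[j]
            )
    return hess


def count_estimable(hessian: np.ndarray, nominal: int,
                    rtol: float = 1e-6) -> int:
    """Estimable-parameter count = numerical rank of the Hessian spectrum.

    Singular values below ``rtol`` times the largest are treated as flat
    (confounded) directions, e.g. the classic terminal phi*p product of the
    fully time-dependent CJS model.
    """
    sv = np.linalg.svd(hessian, compute_uv=False)
    if sv.size == 0 or sv[0] <= 0:
        return nominal
    return int(min(nominal, np.sum(sv > rtol * sv[0])))


def fit_cjs(
    marray: MArray,
    spec: ModelSpec,
    covariates: Mapping[str, object] | None = None,
    options: FitOptions | None = None,
    *,
    n_eff: int | None = None,
) -> FitResult:
    """Fit a constrained CJS model to an m-array by quasi-Newton multistart.

    ``n_eff`` defaults to the total number of observations carried by the
    m-array (initial captures plus resights); it feeds the AICc small-sample
    correction.
    """
    opts = options or FitOptions()
    cohorts = {g: marray.cohorts(g) for g in marray.groups}
    design = build_design(
        spec, marray.occasions, marray.groups, covariates, cohorts=cohorts
    )
    data = _prepare(design, marray)

    def objective(beta: np.ndarray) -> float:
        phi_cells, p_cells = design.cell_values(beta)
        return _nll2_from_cells(data, phi_cells, p_cells)

    k = design.parameter_count_nominal
    rng = np.random.default_rng(opts.seed)
    starts = [np.zeros(k)]
    starts += [rng.normal(0.0, 1.0, size=k) for _ in range(opts.n_starts - 1)]

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={"maxiter": opts.maxiter, "maxfun": 10 ** 6,
                     "gtol": opts.gtol, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        converged = converged or bool(res.success)
    assert best is not None
    if not converged:
        warnings.warn(
            f"model {spec.label()}: no optimizer start converged", RuntimeWarning
        )

    nll2 = float(best.fun)
    deviance = nll2 - data.saturated_nll2
    n_eff_val = int(n_eff if n_eff is not None else marray.n_observations)

    hessian = vcov = None
    np_est = k
    if opts.compute_hessian:
        try:
            hessian = _fd_hessian(objective, best.x, opts.hessian_step)
            np_est = count_estimable(hessian, k, opts.rank_rtol)
            # vcov of beta from the observed information (nll2 = 2 * nll)
            vcov = 2.0 * np.linalg.pinv(hessian, rcond=1e-10, hermitian=True)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(
                f"Hessian evaluation failed ({exc}); using nominal "
                "parameter count",
                RuntimeWarning,
            )
            np_est = k

    aicc = compute_aicc(deviance, np_est, n_eff_val)
    return FitResult(
        spec=spec,
        design=design,
        beta=np.asarray(best.x, dtype=float),
        nll2=nll2,
        deviance=float(deviance),
        np_nominal=k,
        np_estimable=np_est,
        n_eff=n_eff_val,
        aicc=float(aicc),
        converged=converged,
        vcov=vcov,
        hessian=hessian,
    )


def model_selection_table(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits by AICc (ties broken by fewer parameters)."""
    if not fits:
        raise ValueError("empty fit list")
    n_effs = {f.n_eff for f in fits}
    if len(n_effs) > 1:
        raise ValueError(f"mixed effective sample sizes: {sorted(n_effs)}")
    rows = [
        {
            "model": f.name,
            "survival": str(f.spec.survival),
            "resight": str(f.spec.resight),
            "np": f.np_estimable,
            "dev": f.deviance,
            "aicc": f.aicc,
            "converged": f.converged,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values(
        ["aicc", "np"], kind="mergesort"
    ).reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    table["best"] = table.index == 0
    return table
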