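"""Stage-structured matrix projection and the marked-fraction immigration
correction.

The projection matrix is female-based with a pre-breeding census: the
fertility entry carries first-year survival (``sex_ratio * f * phi_1``),
pre-breeders survive with adult survival and recruit into a single breeder
stage according to an age-specific first-breeding schedule ending in certain
recruitment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VitalRates",
    "StageMatrix",
    "ImmigrationEstimate",
    "build_stage_matrix",
    "asymptotic_lambda",
    "project",
    "estimate_immigrants",
]


@dataclass(frozen=True)
class VitalRates:
    """Annual vital rates feeding the projection matrix.

    ``recruitment`` maps age (years) to the conditional probability of first
    breeding at that age; ages must be contiguous and the schedule must end
    with probability 1.
    """

    fecundity: float
    phi_1: float
    phi_ad: float
    recruitment: Mapping[int, float]
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.fecundity < 0:
            raise ValueError("fecundity must be non-negative")
        for name in ("phi_1", "phi_ad", "sex_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        ages = sorted(self.recruitment)
        if not ages:
            raise ValueError("empty recruitment schedule")
        if ages[0] < 2:
            raise ValueError("first possible breeding age must be >= 2 "
                             "(pre-breeding census)")
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValueError("recruitment ages must be contiguous")
        probs = [self.recruitment[a] for a in ages]
        if any(not 0.0 <= r <= 1.0 for r in probs):
            raise ValueError("recruitment probabilities outside [0, 1]")
        if probs[-1] != 1.0:
            raise ValueError("schedule must end with certain recruitment (1)")
        object.__setattr__(self, "recruitment", dict(zip(ages, probs)))


@dataclass(frozen=True)
class StageMatrix:
    """Non-negative projection matrix, ``n_{t+1} = A @ n_t``."""

    matrix: np.ndarray
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("projection matrix must be square")
        if a.shape[0] != len(self.stages):
            raise ValueError("stage labels do not match matrix dimension")
        if (a < 0).any():
            raise ValueError("projection matrix entries must be non-negative")
        object.__setattr__(self, "matrix", a)


def build_stage_matrix(rates: VitalRates) -> StageMatrix:
    """Assemble the pre-breeding-census matrix from vital rates.

    Stages are pre-breeders of age 1 .. a_max-1 plus one breeder stage;
    a pre-breeder of age ``j`` survives with ``phi_ad`` and recruits with
    the schedule probability of age ``j+1``, breeders survive with
    ``phi_ad`` and produce ``sex_ratio * f * phi_1`` one-year-olds.
    """
    ages = sorted(rates.recruitment)
    a_max = ages[-1]
    n_pre = a_max - 1
    stages = tuple(f"pre{j}" for j in range(1, n_pre + 1)) + ("breeder",)
    k = n_pre + 1
    a = np.zeros((k, k))
    b = k - 1  # breeder index
    a[0, b] = rates.sex_ratio * rates.fecundity * rates.phi_1
    a[b, b] = rates.phi_ad
    for j in range(1, n_pre + 1):  # pre-breeder age j at stage index j-1
        r_next = rates.recruitment.get(j + 1, 0.0)
        a[b, j - 1] += rates.phi_ad * r_next
        if j < n_pre:
            a[j, j - 1] = rates.phi_ad * (1.0 - r_next)
    return StageMatrix(a, stages)


def asymptotic_lambda(a: StageMatrix | np.ndarray) -> float:
    """Dominant eigenvalue modulus of a non-negative projection matrix."""
    mat = a.matrix if isinstance(a, StageMatrix) else np.asarray(a, float)
    if (mat < 0).any():
        raise ValueError("projection matrix entries must be non-negative")
    return float(np.max(np.abs(np.linalg.eigvals(mat))))


def project(
    matrices: StageMatrix | Mapping[int, StageMatrix] | Sequence[StageMatrix],
    n0: Sequence[float],
    years: int,
) -> tuple[np.ndarray, float]:
    """Project ``n_{t+1} = A_t n_t`` and report total sizes per year.

    ``matrices`` may be a single constant matrix, a sequence of annual
    matrices (length ``years``), or a 0-based year->matrix mapping.
    Returns the (years+1, stages) trajectory and the geometric-mean growth
    of the total, ``(N_T / N_0)^(1/years)`` (0 if the population hits 0).
    """
    n = np.asarray(n0, dtype=float)
    if isinstance(matrices, StageMatrix):
        seq = [matrices] * years
    elif isinstance(matrices, Mapping):
        seq = [matrices[t] for t in range(years)]
    else:
        seq = list(matrices)
        if len(seq) != years:
            raise ValueError(f"{len(seq)} matrices for {years} years")
    dim = seq[0].matrix.shape[0]
    if n.shape != (dim,):
        raise ValueError(f"initial vector length {n.size} != {dim} stages")
    traj = np.empty((years + 1, dim))
    traj[0] = n
    for t, a in enumerate(seq):
        if a.matrix.shape[0] != dim:
            raise ValueError("annual matrices differ in dimension")
        n = a.matrix @ n
        traj[t + 1] = n
    total0, total_t = traj[0].sum(), traj[-1].sum()
    if total0 <= 0 or total_t <= 0:
        growth = 0.0
    else:
        growth = float((total_t / total0) ** (1.0 / years))
    return traj, growth


@dataclass(frozen=True)
class ImmigrationEstimate:
    year: int
    observed_immigrants: int
    marked_fraction: float
    resight_prob: float
    corrected_count: float
    proportion_of_breeders: float


def estimate_immigrants(
    observed: int,
    marked_fraction: float,
    resight_prob: float,
    n_breeders: int,
    year: int = 0,
) -> ImmigrationEstimate:
    """Correct observed marked immigrants by marking and resighting rates.

    ``corrected = observed / (m_r * p_s)`` scales the marked immigrants seen
    at the destination by the fraction marked at the origin and the annual
    resighting probability at the destination.
    """
    if not 0.0 < marked_fraction <= 1.0:
        raise ValueError("marked fraction must be in (0, 1]")
    if not 0.0 < resight_prob <= 1.0:
        raise ValueError("resighting probability must be in (0, 1]")
    if n_breeders <= 0:
        raise ValueError("breeder count must be positive")
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    corrected = observed / (marked_fraction * resight_prob)
    return ImmigrationEstimate(
        year=year,
        observed_immigrants=observed,
        marked_fraction=marked_fraction,
        resight_prob=resight_prob,
        corrected_count=float(corrected),
        proportion_of_breeders=float(corrected / n_breeders),
    )
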