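"""Goodness-of-fit of the fully time-dependent CJS model.

The global test is assembled from per-occasion contingency-table components
in the U-CARE tradition:

* TEST3.SR -- newly vs previously marked among birds encountered at ``i``,
  against ever re-encountered later (transience / marking effects).
* TEST3.Sm -- the same split, against the occasion of next encounter
  (conditional on re-encounter, hence independent of SR).
* TEST2.CT -- encountered at ``i`` or not (among birds marked before ``i``
  and seen again later), against next encounter at ``i+1`` vs later
  (trap-dependence).
* TEST2.CL -- the same split, against the exact occasion of next encounter
  conditional on it being after ``i+1`` (hence independent of CT).

Each table is pooled (expected count < 2, columns merged toward their left
neighbour) before a Pearson chi-square; degenerate tables (df 0 or an empty
row margin) are flagged and excluded from the global sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from cmrpop.encounter_data import CaptureHistorySet

__all__ = ["GofComponent", "GofResult", "component_tests", "global_gof"]

POOL_THRESHOLD = 2.0


@dataclass
class GofComponent:
    name: str  # TEST3.SR | TEST3.Sm | TEST2.CT | TEST2.CL
    group: str
    occasion: int  # calendar year
    chi2: float
    df: int
    table: np.ndarray
    degenerate: bool


@dataclass
class GofResult:
    chi2: float
    df: int
    p: float
    components: list[GofComponent]


def _pool_columns(table: np.ndarray) -> np.ndarray:
    """Merge columns with small expected counts into their left neighbour."""
    table = table.astype(float)
    while table.shape[1] > 1:
        n = table.sum()
        if n == 0:
            break
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        small = np.where(expected.min(axis=0) < POOL_THRESHOLD)[0]
        if small.size == 0:
            break
        j = int(small[-1])
        k = j - 1 if j > 0 else j + 1
        table[:, k] += table[:, j]
        table = np.delete(table, j, axis=1)
    return table


def _pearson(table: np.ndarray) -> tuple[float, int, bool]:
    pooled = _pool_columns(table)
    rows = pooled[pooled.sum(axis=1) > 0]
    if rows.shape[0] < 2 or rows.shape[1] < 2:
        return 0.0, 0, True
    n = rows.sum()
    expected = np.outer(rows.sum(axis=1), rows.sum(axis=0)) / n
    if expected.min() < POOL_THRESHOLD:
        return 0.0, 0, True
    chi2 = float(((rows - expected) ** 2 / expected).sum())
    df = (rows.shape[0] - 1) * (rows.shape[1] - 1)
    return chi2, df, False


def _first_after(det: np.ndarray, i: int) -> np.ndarray:
    """Index of the first detection strictly after occasion i (-1 if none)."""
    later = det[:, i + 1:]
    has = later.any(axis=1)
    idx = np.where(has, later.argmax(axis=1) + i + 1, -1)
    return idx


def _components_for_group(
    det: np.ndarray, group: str, occasions: tuple[int, ...]
) -> list[GofComponent]:
    t = det.shape[1]
    cohort = det.argmax(axis=1)
    out: list[GofComponent] = []
    for i in range(1, t - 1):
        year = occasions[i]
        nxt = _first_after(det, i)

        # --- TEST3: birds encountered at occasion i
        at_i = det[:, i] == 1
        new = at_i & (cohort == i)
        old = at_i & (cohort < i)
        seen_later = nxt >= 0
        sr = np.array(
            [
                [np.sum(new & seen_later), np.sum(new & ~seen_later)],
                [np.sum(old & seen_later), np.sum(old & ~seen_later)],
            ],
            dtype=float,
        )
        chi2, df, degen = _pearson(sr)
        out.append(GofComponent("TEST3.SR", group, year, chi2, df, sr, degen))

        cols = range(i + 1, t)
        sm = np.array(
            [
                [np.sum(new & (nxt == j)) for j in cols],
                [np.sum(old & (nxt == j)) for j in cols],
            ],
            dtype=float,
        )
        if sm.shape[1] >= 2:
            chi2, df, degen = _pearson(sm)
            out.append(
                GofComponent("TEST3.Sm", group, year, chi2, df, sm, degen)
            )

        # --- TEST2: birds marked before i and re-encountered after i
        premarked = (cohort < i) & seen_later
        row_seen = premarked & at_i
        row_miss = premarked & ~at_i
        ct = np.array(
            [
                [np.sum(row_seen & (nxt == i + 1)), np.sum(row_seen & (nxt > i + 1))],
                [np.sum(row_miss & (nxt == i + 1)), np.sum(row_miss & (nxt > i + 1))],
            ],
            dtype=float,
        )
        chi2, df, degen = _pearson(ct)
        out.append(GofComponent("TEST2.CT", group, year, chi2, df, ct, degen))

        cl_cols = range(i + 2, t)
        if len(cl_cols) >= 2:
            cl = np.array(
                [
                    [np.sum(row_seen & (nxt == j)) for j in cl_cols],
                    [np.sum(row_miss & (nxt == j)) for j in cl_cols],
                ],
                dtype=float,
            )
            chi2, df, degen = _pearson(cl)
            out.append(
                GofComponent("TEST2.CL", group, year, chi2, df, cl, degen)
            )
    return out


def component_tests(
    chs: CaptureHistorySet, by_cohort: bool = False
) -> list[GofComponent]:
    """Compute all GOF components, per group.

    With ``by_cohort=True`` every release cohort is tested separately (the
    per-cohort protocol); TEST3 is then structurally degenerate because all
    birds of a cohort are newly marked together, which is expected and
    handled by the degeneracy flags.
    """
    if len(chs.occasions) < 3:
        raise ValueError("goodness-of-fit needs at least three occasions")
    components: list[GofComponent] = []
    for g in chs.groups:
        det = chs.detection_matrix(g)
        if by_cohort:
            cohort = det.argmax(axis=1)
            for c in sorted(set(cohort)):
                sub = det[cohort == c]
                components.extend(
                    _components_for_group(sub, f"{g}/cohort{chs.occasions[c]}",
                                          chs.occasions)
                )
        else:
            components.extend(_components_for_group(det, g, chs.occasions))
    return components


def global_gof(components: list[GofComponent]) -> GofResult:
    """Sum non-degenerate components into the global chi-square test."""
    if not components:
        raise ValueError("empty component list")
    live = [c for c in components if not c.degenerate and c.df > 0]
    if not live:
        raise ValueError("all goodness-of-fit components are degenerate")
    chi2 = float(sum(c.chi2 for c in live))
    df = int(sum(c.df for c in live))
    return GofResult(chi2, df, float(stats.chi2.sf(chi2, df)), components)
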