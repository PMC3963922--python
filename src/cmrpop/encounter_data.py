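"""Encounter-history containers, file I/O and m-array reduction.

Individuals are marked as fledglings, so the first detection of a history
defines its release cohort and ``age = occasion - cohort`` throughout.
Histories are reduced to cohort-structured m-arrays (releases and
first-re-encounter counts), the sufficient statistic of the CJS likelihood.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EncounterHistory",
    "CaptureHistorySet",
    "MArray",
    "MArrayRow",
    "read_histories",
    "write_histories",
    "build_marray",
    "summarize",
]


class EncounterFormatError(ValueError):
    """Raised when an encounter-history file violates its dialect."""


@dataclass(frozen=True)
class EncounterHistory:
    """One marked individual's 0/1 detection vector over the occasion axis."""

    individual_id: str
    group: str
    detections: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.detections:
            raise ValueError("empty detection vector")
        if any(d not in (0, 1) for d in self.detections):
            raise ValueError(f"{self.individual_id}: detections must be 0/1")
        if sum(self.detections) < 1:
            raise ValueError(f"{self.individual_id}: at least one detection required")

    @property
    def cohort(self) -> int:
        """0-based index of the release occasion (first detection)."""
        return self.detections.index(1)

    @property
    def n_detections(self) -> int:
        return int(sum(self.detections))


@dataclass(frozen=True)
class CaptureHistorySet:
    """A collection of encounter histories sharing one occasion axis."""

    occasions: tuple[int, ...]
    histories: tuple[EncounterHistory, ...]

    def __post_init__(self) -> None:
        if len(self.occasions) < 2:
            raise ValueError("need at least two occasions")
        if list(self.occasions) != sorted(set(self.occasions)):
            raise ValueError("occasions must be strictly increasing")
        t = len(self.occasions)
        for h in self.histories:
            if len(h.detections) != t:
                raise EncounterFormatError(
                    f"{h.individual_id}: history length {len(h.detections)} "
                    f"!= {t} occasions"
                )

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for h in self.histories:
            seen.setdefault(h.group, None)
        return tuple(seen)

    @property
    def n_individuals(self) -> int:
        return len(self.histories)

    @property
    def n_observations(self) -> int:
        """Total number of detections (initial captures plus resights)."""
        return int(sum(h.n_detections for h in self.histories))

    def subset(self, group: str) -> "CaptureHistorySet":
        return CaptureHistorySet(
            self.occasions,
            tuple(h for h in self.histories if h.group == group),
        )

    def merge(self, other: "CaptureHistorySet") -> "CaptureHistorySet":
        if self.occasions != other.occasions:
            raise ValueError("cannot merge sets with different occasion axes")
        return CaptureHistorySet(self.occasions, self.histories + other.histories)

    def detection_matrix(self, group: str | None = None) -> np.ndarray:
        hs = self.histories if group is None else tuple(
            h for h in self.histories if h.group == group
        )
        return np.array([h.detections for h in hs], dtype=np.int64)


@dataclass
class MArrayRow:
    """Releases at one occasion for one cohort, with first-re-encounter counts.

    ``m[j]`` counts birds from this release first re-encountered at occasion
    ``j`` (0-based); entries at ``j <= release`` are structurally zero.
    """

    group: str
    cohort: int
    release: int
    released: int
    m: np.ndarray
    never: int

    def check(self) -> None:
        if self.released != int(self.m.sum()) + self.never:
            raise AssertionError("m-array conservation violated")
        if (self.m < 0).any() or self.never < 0 or self.released < 0:
            raise AssertionError("negative m-array count")
        if self.m[: self.release + 1].any():
            raise AssertionError("re-encounter before release")


@dataclass
class MArray:
    """Cohort-structured m-array for one or more groups."""

    occasions: tuple[int, ...]
    rows: list[MArrayRow]
    n_observations: int = 0

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.group, None)
        return tuple(seen)

    def cohorts(self, group: str) -> tuple[int, ...]:
        return tuple(sorted({r.cohort for r in self.rows if r.group == group}))

    def totals(self, group: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Aggregate (R_i, m_ij, never_i) over cohorts for presentation.

        Returns releases per occasion, the first-re-encounter matrix and the
        never-seen-again counts, all 0-based over the occasion axis.
        """
        t = len(self.occasions)
        releases = np.zeros(t, dtype=np.int64)
        m = np.zeros((t, t), dtype=np.int64)
        never = np.zeros(t, dtype=np.int64)
        for r in self.rows:
            if r.group != group:
                continue
            releases[r.release] += r.released
            m[r.release] += r.m
            never[r.release] += r.never
        return releases, m, never


_INP_LINE = re.compile(r"^(?P<hist>[01]+)\s+(?P<counts>[-\d\s]+?)\s*;\s*(?:/\*.*)?$")


def read_histories(
    path: str | Path,
    dialect: str = "tabular",
    *,
    occasions: Sequence[int] | None = None,
    groups: Sequence[str] | None = None,
) -> CaptureHistorySet:
    """Read encounter histories from a MARK-style ``.inp`` or a tabular file.

    Parameters
    ----------
    path:
        Plain-text input file.
    dialect:
        ``"inp"`` -- lines of the form ``"1100 3;"`` (detection string, one
        frequency column per group, terminating semicolon).  The occasion
        axis carries calendar years and must be supplied explicitly via
        ``occasions``; it is never inferred from string length.
        ``"tabular"`` -- delimited text with header ``id,group,<year>,...``
        and one 0/1 row per individual.
    occasions:
        Calendar years of the occasions (required for ``inp``).
    groups:
        Group (colony) labels for the ``inp`` frequency columns; defaults to
        ``g1, g2, ...``.
    """
    path = Path(path)
    if dialect == "inp":
        if occasions is None:
            raise ValueError("the 'inp' dialect requires an explicit occasion axis")
        return _read_inp(path, tuple(int(y) for y in occasions), groups)
    if dialect == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_inp(
    path: Path, occasions: tuple[int, ...], groups: Sequence[str] | None
) -> CaptureHistorySet:
    histories: list[EncounterHistory] = []
    n_groups: int | None = None
    counter = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("/*"):
                continue
            match = _INP_LINE.match(line)
            if match is None:
                raise EncounterFormatError(
                    f"{path}:{lineno}: malformed inp line {line!r}"
                )
            hist = match.group("hist")
            if len(hist) != len(occasions):
                raise EncounterFormatError(
                    f"{path}:{lineno}: history length {len(hist)} != "
                    f"{len(occasions)} occasions"
                )
            counts = [int(tok) for tok in match.group("counts").split()]
            if n_groups is None:
                n_groups = len(counts)
            elif len(counts) != n_groups:
                raise EncounterFormatError(
                    f"{path}:{lineno}: expected {n_groups} frequency columns, "
                    f"got {len(counts)}"
                )
            labels = (
                list(groups)
                if groups is not None
                else [f"g{i + 1}" for i in range(n_groups)]
            )
            if len(labels) != n_groups:
                raise EncounterFormatError(
                    f"{path}:{lineno}: {len(labels)} group labels for "
                    f"{n_groups} frequency columns"
                )
            detections = tuple(int(c) for c in hist)
            if sum(detections) == 0:
                raise EncounterFormatError(
                    f"{path}:{lineno}: history with zero detections"
                )
            for label, count in zip(labels, counts):
                if count < 0:
                    raise EncounterFormatError(
                        f"{path}:{lineno}: negative frequency (losses on "
                        "capture are not modelled)"
                    )
                for _ in range(count):
                    counter += 1
                    histories.append(
                        EncounterHistory(f"i{counter}", label, detections)
                    )
    return CaptureHistorySet(occasions, tuple(histories))


def _read_tabular(path: Path) -> CaptureHistorySet:
    with open(path, encoding="utf-8", newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise EncounterFormatError(f"{path}: empty file") from None
        if len(header) < 3 or header[0].lower() != "id":
            raise EncounterFormatError(
                f"{path}:1: expected header 'id,group,<year>,...'"
            )
        try:
            occasions = tuple(int(y) for y in header[2:])
        except ValueError as exc:
            raise EncounterFormatError(f"{path}:1: non-integer year column: {exc}")
        histories = []
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) != len(header):
                raise EncounterFormatError(
                    f"{path}:{lineno}: {len(row)} fields, expected {len(header)}"
                )
            flags = []
            for cell in row[2:]:
                if cell.strip() not in ("0", "1"):
                    raise EncounterFormatError(
                        f"{path}:{lineno}: illegal detection flag {cell!r}"
                    )
                flags.append(int(cell))
            histories.append(EncounterHistory(row[0], row[1], tuple(flags)))
    return CaptureHistorySet(occasions, tuple(histories))


def write_histories(
    chs: CaptureHistorySet, path: str | Path, dialect: str = "tabular"
) -> None:
    """Write a history set in one of the two supported dialects."""
    path = Path(path)
    if dialect == "tabular":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "group"] + [str(y) for y in chs.occasions])
            for h in chs.histories:
                writer.writerow([h.individual_id, h.group] + list(h.detections))
    elif dialect == "inp":
        group_order = chs.groups
        with open(path, "w", encoding="utf-8") as fh:
            for h in chs.histories:
                hist = "".join(str(d) for d in h.detections)
                counts = " ".join(
                    "1" if g == h.group else "0" for g in group_order
                )
                fh.write(f"{hist} {counts};\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def build_marray(chs: CaptureHistorySet) -> MArray:
    """Reduce a history set to its cohort-structured m-array.

    Every detection of a surviving bird re-enters the releases at that
    occasion (standard CJS re-release convention; resights only, no losses
    on capture).  Releases at the final occasion carry no information and
    are dropped.
    """
    t = len(chs.occasions)
    rows: dict[tuple[str, int, int], MArrayRow] = {}

    def row(group: str, cohort: int, release: int) -> MArrayRow:
        key = (group, cohort, release)
        if key not in rows:
            rows[key] = MArrayRow(
                group, cohort, release, 0, np.zeros(t, dtype=np.int64), 0
            )
        return rows[key]

    for h in chs.histories:
        dets = [i for i, d in enumerate(h.detections) if d]
        for i, j in zip(dets, dets[1:]):
            r = row(h.group, dets[0], i)
            r.released += 1
            r.m[j] += 1
        last = dets[-1]
        if last < t - 1:
            r = row(h.group, dets[0], last)
            r.released += 1
            r.never += 1

    ordered = [rows[k] for k in sorted(rows)]
    for r in ordered:
        r.check()
    return MArray(chs.occasions, ordered, n_observations=chs.n_observations)


def summarize(chs: CaptureHistorySet) -> dict:
    """Per-group and overall counts: individuals, observations, cohort sizes."""
    out: dict = {
        "n_individuals": chs.n_individuals,
        "n_observations": chs.n_observations,
        "groups": {},
    }
    for g in chs.groups:
        sub = [h for h in chs.histories if h.group == g]
        cohorts: dict[int, int] = {}
        for h in sub:
            year = chs.occasions[h.cohort]
            cohorts[year] = cohorts.get(year, 0) + 1
        out["groups"][g] = {
            "n_individuals": len(sub),
            "n_observations": int(sum(h.n_detections for h in sub)),
            "releases_per_cohort": dict(sorted(cohorts.items())),
        }
    return out
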