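"""Internal-browning severity index and incidence from graded fruit cohorts.

Grades run 0 (clean) to 5 (worst).  The severity index of a cohort is the
grade-weighted fruit count over five times the cohort size, scaled to 100:
index = 100 * sum(grade * count) / (5 * N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .annotation_io import round2

__all__ = ["IBCohort", "ib_index", "ib_incidence", "read_cohorts_tsv", "write_ib_report"]

MAX_GRADE = 5


@dataclass(frozen=True)
class IBCohort:
    """Per-grade fruit counts of one treatment group at one storage day."""

    grade_counts: Mapping[int, int]
    n_total: int
    group: str = ""
    day: int | None = None

    def __post_init__(self) -> None:
        for grade, count in self.grade_counts.items():
            if not 0 <= grade <= MAX_GRADE:
                raise ValueError(f"grade {grade} outside 0..{MAX_GRADE}")
            if count < 0:
                raise ValueError(f"negative count at grade {grade}")
        if sum(self.grade_counts.values()) > self.n_total:
            raise ValueError("graded fruits exceed cohort size")
        object.__setattr__(self, "grade_counts", dict(self.grade_counts))

    @property
    def n_affected(self) -> int:
        """Fruits with visible spots: grade >= 1."""
        return sum(c for g, c in self.grade_counts.items() if g >= 1)


def ib_index(cohort: IBCohort) -> float:
    """Severity index in [0, 100]; ungraded remainder counts as grade 0."""
    if cohort.n_total <= 0:
        raise ValueError("cohort must contain at least one fruit")
    weighted = sum(g * c for g, c in cohort.grade_counts.items())
    return round2(100.0 * weighted / (MAX_GRADE * cohort.n_total))


def ib_incidence(n_affected: int, n_total: int) -> float:
    """Percentage of fruits showing spots."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_affected <= n_total:
        raise ValueError("n_affected must lie in [0, n_total]")
    return round2(100.0 * n_affected / n_total)


def read_cohorts_tsv(path: str | Path) -> list[IBCohort]:
    """Cohort table: group, day, grade, count (one row per grade level)."""
    rows: dict[tuple[str, int], dict[int, int]] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines:
        if not line.strip() or line.lower().startswith("group"):
            continue
        group, day, grade, count = line.split("\t")
        key = (group, int(day))
        rows.setdefault(key, {})
        rows[key][int(grade)] = rows[key].get(int(grade), 0) + int(count)
    return [
        IBCohort(grade_counts=counts, n_total=sum(counts.values()), group=g, day=d)
        for (g, d), counts in sorted(rows.items())
    ]


def write_ib_report(cohorts: Iterable[IBCohort], path: str | Path) -> None:
    lines = ["group\tday\tn_total\tn_affected\tincidence_pct\tib_index"]
    for c in cohorts:
        lines.append(
            f"{c.group}\t{c.day}\t{c.n_total}\t{c.n_affected}"
            f"\t{ib_incidence(c.n_affected, c.n_total)}\t{ib_index(c)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
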