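"""Genotype-by-sex contingency tables and the two-sided Fisher exact test.

Individuals typed by the duplex assay carry an xx or xy genotype and a
phenotypic sex; under a male-heterogametic system the xy genotype should
track maleness.  The association is tested on the 2x2 table with the
probability-mass two-sided criterion: sum the hypergeometric probability of
every table with the observed margins that is no more probable than the
observed one (with a small relative tolerance guarding floating-point ties).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from math import exp, lgamma
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "IndividualCall",
    "SexTable2x2",
    "FisherResult",
    "tabulate",
    "fisher_two_sided",
    "load_calls_tsv",
]

TIE_REL_TOL = 1e-7


@dataclass(frozen=True)
class IndividualCall:
    """One individual's phenotypic sex (F/M) and assay genotype (xx/xy)."""

    individual: str
    sex: Optional[str]
    genotype: Optional[str]

    @property
    def complete(self) -> bool:
        return self.sex in ("F", "M") and self.genotype in ("xx", "xy")


@dataclass(frozen=True)
class SexTable2x2:
    """Counts a = xy females, b = xy males, c = xx females, d = xx males."""

    a: int
    b: int
    c: int
    d: int
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(xy row, xx row, female column, male column) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class FisherResult:
    p_two_sided: float
    observed_probability: float

    def rounded(self, decimals: int = 4) -> float:
        """Display rounding used in association reports."""
        return round(self.p_two_sided, decimals)


def tabulate(calls: Iterable[IndividualCall]) -> SexTable2x2:
    """Count individuals by (genotype, sex); incomplete records are excluded
    from the table and tallied in ``excluded``."""
    a = b = c = d = excluded = 0
    for call in calls:
        if not call.complete:
            excluded += 1
        elif call.genotype == "xy":
            a, b = (a + 1, b) if call.sex == "F" else (a, b + 1)
        else:
            c, d = (c + 1, d) if call.sex == "F" else (c, d + 1)
    return SexTable2x2(a, b, c, d, excluded)


def _log_table_prob(a: int, r1: int, r2: int, c1: int, c2: int) -> float:
    """Log hypergeometric probability of the table with top-left cell ``a``
    given row totals (r1, r2) and column totals (c1, c2)."""
    n = r1 + r2
    b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
    return (
        lgamma(r1 + 1)
        + lgamma(r2 + 1)
        + lgamma(c1 + 1)
        + lgamma(c2 + 1)
        - lgamma(n + 1)
        - lgamma(a + 1)
        - lgamma(b + 1)
        - lgamma(c + 1)
        - lgamma(d + 1)
    )


def fisher_two_sided(table: SexTable2x2) -> FisherResult:
    """Exact two-sided Fisher test by enumeration over the observed margins.

    p is the sum of hypergeometric probabilities of every table at most as
    probable as the observed one (relative tie tolerance 1e-7).  Raises on an
    all-zero table, where the test is undefined.
    """
    r1, r2, c1, c2 = table.margins
    if table.n == 0:
        raise ValueError("Fisher test is undefined on an all-zero table")
    p_obs = exp(_log_table_prob(table.a, r1, r2, c1, c2))
    cutoff = p_obs * (1.0 + TIE_REL_TOL)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p = 0.0
    for a in range(lo, hi + 1):
        prob = exp(_log_table_prob(a, r1, r2, c1, c2))
        if prob <= cutoff:
            p += prob
    return FisherResult(p_two_sided=min(p, 1.0), observed_probability=p_obs)


def load_calls_tsv(path: str | Path) -> list[IndividualCall]:
    """Read individuals from a TSV with columns id, sex, genotype (header optional)."""
    out: list[IndividualCall] = []
    with Path(path).open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].lower() in ("id", "individual"):
                continue
            ind = row[0]
            sex = row[1].strip().upper() if len(row) > 1 and row[1].strip() else None
            gt = row[2].strip().lower() if len(row) > 2 and row[2].strip() else None
            out.append(IndividualCall(ind, sex, gt))
    return out


def write_association_tsv(
    rows: Iterable[tuple[str, SexTable2x2, FisherResult]], path: str | Path
) -> None:
    """Write per-group association results in the published report layout:
    one xy and one xx row per group, with the 4-decimal p-value on the xy row."""
    with Path(path).open("w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["Group", "Genotype", "Females", "Males", "p_value", "excluded"])
        for name, table, result in rows:
            writer.writerow(
                [name, "xy", table.a, table.b, f"{result.rounded():.4f}", table.excluded]
            )
            writer.writerow([name, "xx", table.c, table.d, "", ""])
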