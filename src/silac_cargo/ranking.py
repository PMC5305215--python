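"""Replicate aggregation by order statistics and percentile cargo calls.

A protein quantified in two replicates contributes the lower of its two
Z-scores; one quantified in all three contributes the middle one. Ranking by
this "second-largest Z" (the 2nd-Z-ranking) keeps proteins that scored high
in at least two replicates. Ranking the three-replicate proteins by their
minimum Z (the 3rd-Z-ranking) demands consistency across all replicates and
trades recall for specificity. Proteins with a single value are excluded.

Candidate cargo sets are called by percentile: the top 15% of the
2nd-Z-ranking (high sensitivity) and the top 4% of the 3rd-Z-ranking (high
specificity), with the member count given by floor(N * pct / 100).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .errors import DomainError, UsageError
from .ratio import RatioRecord

__all__ = [
    "Statistic",
    "Criterion",
    "RankingEntry",
    "RankedProtein",
    "CargoSet",
    "assemble",
    "order_statistic",
    "rank_proteins",
    "cutoff_count",
    "call_cargo_set",
]


class Statistic(str, enum.Enum):
    SECOND_Z = "second_z"
    THIRD_Z = "third_z"


class Criterion(str, enum.Enum):
    """Named cargo-calling criteria: statistic plus default percentile."""

    SECOND_Z_15 = "second_z_15"
    THIRD_Z_4 = "third_z_4"

    @property
    def statistic(self) -> Statistic:
        return Statistic.SECOND_Z if self is Criterion.SECOND_Z_15 else Statistic.THIRD_Z

    @property
    def default_pct(self) -> float:
        return 15.0 if self is Criterion.SECOND_Z_15 else 4.0


@dataclass(frozen=True)
class RankingEntry:
    """A protein's Z-score vector across replicates and its order statistics."""

    accession: str
    z_values: tuple[float, ...]  # ordered by replicate index

    @property
    def n_values(self) -> int:
        return len(self.z_values)

    @property
    def second_z(self) -> float:
        return order_statistic(self.z_values, 2)

    @property
    def third_z(self) -> float | None:
        return order_statistic(self.z_values, 3) if self.n_values == 3 else None


@dataclass(frozen=True)
class RankedProtein:
    """One row of a realized ranking (entry plus rank and percentile)."""

    rank: int
    accession: str
    statistic: float
    z_values: tuple[float, ...]
    n_values: int
    percentile: float


@dataclass(frozen=True)
class CargoSet:
    """A called candidate-cargo list for one receptor, in rank order."""

    receptor: str
    criterion: Criterion
    members: tuple[str, ...]


def assemble(replicate_tables: Mapping[int, Sequence[RatioRecord]] | Sequence[Sequence[RatioRecord]]) -> list[RankingEntry]:
    """Collect per-replicate ratio records into per-protein Z-score vectors.

    Accepts 2 or 3 replicate tables (a mapping keyed by replicate index, or a
    sequence in replicate order). Proteins with a single Z value are excluded;
    those with two or three are retained. Entries are returned sorted by
    accession; the z_values tuple is ordered by replicate index.
    """
    if isinstance(replicate_tables, Mapping):
        items = sorted(replicate_tables.items())
    else:
        items = list(enumerate(replicate_tables, start=1))
    if not 2 <= len(items) <= 3:
        raise UsageError(f"need 2 or 3 replicate tables, got {len(items)}")
    per_protein: dict[str, list[tuple[int, float]]] = {}
    for rep_index, table in items:
        for rec in table:
            per_protein.setdefault(rec.accession, []).append((rep_index, rec.z))
    entries = []
    for acc in sorted(per_protein):
        zs = [z for _, z in sorted(per_protein[acc])]
        if len(zs) >= 2:
            entries.append(RankingEntry(accession=acc, z_values=tuple(zs)))
    return entries


def order_statistic(z_values: Sequence[float], k: int) -> float:
    """The k-th largest of 2-3 values (k=2: lower of two / middle of three)."""
    if k not in (2, 3):
        raise DomainError(f"k must be 2 or 3, got {k}")
    if k > len(z_values):
        raise DomainError(f"k={k} exceeds the number of values ({len(z_values)})")
    return sorted(z_values, reverse=True)[k - 1]


def _sort_key(entry: RankingEntry, statistic: Statistic):
    k = 2 if statistic is Statistic.SECOND_Z else 3
    stat = order_statistic(entry.z_values, k)
    # Ties: larger sum of the remaining order statistics first, then accession.
    remaining = sum(entry.z_values) - stat
    return (-stat, -remaining, entry.accession)


def rank_proteins(entries: Iterable[RankingEntry], statistic: Statistic | str) -> list[RankedProtein]:
    """Rank entries descending by the requested order statistic.

    For the 3rd-Z statistic only proteins with three values are eligible;
    callers should have filtered via :func:`assemble` but a missing statistic
    here is a usage error. Ranks are 1..N without gaps; ties are broken by the
    larger sum of the remaining order statistics, then lexicographically by
    accession, so output is byte-stable across runs.
    """
    statistic = Statistic(statistic)
    entries = list(entries)
    if statistic is Statistic.THIRD_Z:
        missing = [e.accession for e in entries if e.n_values < 3]
        if missing:
            raise UsageError(
                f"{len(missing)} entries lack a third Z value (e.g. {missing[0]!r}); "
                "filter to three-replicate proteins before 3rd-Z ranking"
            )
    ordered = sorted(entries, key=lambda e: _sort_key(e, statistic))
    n = len(ordered)
    k = 2 if statistic is Statistic.SECOND_Z else 3
    return [
        RankedProtein(
            rank=i,
            accession=e.accession,
            statistic=order_statistic(e.z_values, k),
            z_values=e.z_values,
            n_values=e.n_values,
            percentile=100.0 * i / n,
        )
        for i, e in enumerate(ordered, start=1)
    ]


def cutoff_count(n: int, pct: float) -> int:
    """Number of proteins in the top ``pct`` percent: floor(n * pct / 100)."""
    if not 0 < pct <= 100:
        raise DomainError(f"pct must be in (0, 100], got {pct}")
    if n < 0:
        raise DomainError(f"n must be non-negative, got {n}")
    return math.floor(n * pct / 100)


def call_cargo_set(
    ranking: Sequence[RankedProtein],
    receptor: str,
    criterion: Criterion | str,
    pct: float | None = None,
    count: int | None = None,
) -> CargoSet:
    """Call the candidate-cargo set at a percentile cutoff.

    ``pct`` overrides the criterion's default percentile; ``count`` overrides
    the computed member count outright (for reproducing externally fixed set
    sizes at boundary ties).
    """
    if not ranking:
        raise UsageError("cannot call a cargo set from an empty ranking")
    criterion = Criterion(criterion)
    if count is None:
        count = cutoff_count(len(ranking), pct if pct is not None else criterion.default_pct)
    members = tuple(r.accession for r in ranking[:count])
    return CargoSet(receptor=receptor, criterion=criterion, members=members)
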