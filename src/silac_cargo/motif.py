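"""NLS motif scanning and ranked-list motif-density profiling.

Patterns are declarative: an ordered list of elements over amino-acid
classes with bounded gaps, serializable to and from plain dictionaries (and
hence YAML config). Shipped defaults cover the canonical PY-NLS consensus —
a C-terminal R/K/H-X(2-5)-P-Y element preceded, within a bounded linker, by
either a hydrophobic N-terminal element (Phi-[GAS]-Phi-Phi with Phi one of
W/F/Y/L/I/V/M) or a basic one (at least 4 K/R within a 6-residue window) —
and the SRSRSR hexapeptide marker of SR-rich splicing factors. Every residue
class and gap bound can be overridden in config.

Structural-disorder context is deliberately not evaluated; the scan is
purely sequence-pattern based.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, UsageError

__all__ = [
    "MotifPattern",
    "MotifHit",
    "DensityPoint",
    "default_py_nls_patterns",
    "sr_repeat_pattern",
    "scan",
    "scan_sequences",
    "motif_positive",
    "windowed_density",
]

HYDROPHOBIC = "WFYLIVM"

_MAX_GAP = 1000  # hard bound: patterns must not contain unbounded repeats


@dataclass(frozen=True)
class MotifHit:
    """One match: 1-based inclusive residue coordinates."""

    accession: str
    pattern: str
    start: int
    end: int


@dataclass(frozen=True)
class DensityPoint:
    position: int  # first rank covered by the window
    pct: float     # percent motif-positive proteins in the window


class MotifPattern:
    """A compiled, declarative sequence pattern.

    ``elements`` is a sequence of dicts, each one of:

    - ``{"any_of": "RKH"}`` — one residue from the class;
    - ``{"literal": "PY"}`` — an exact substring;
    - ``{"gap": [lo, hi]}`` — between lo and hi arbitrary residues;
    - ``{"enriched": {"residues": "KR", "min_count": 4, "window": 6}}`` —
      a fixed-width window containing at least ``min_count`` residues from
      the class.
    """

    def __init__(self, name: str, elements: Sequence[Mapping]):
        self.name = name
        self.elements = tuple(dict(e) for e in elements)
        self._regex = re.compile(f"(?=({self._build_regex()}))")

    def _build_regex(self) -> str:
        parts = []
        for el in self.elements:
            if len(el) != 1:
                raise ConfigError(f"pattern {self.name!r}: element must have exactly one key, got {el!r}")
            (kind, val), = el.items()
            if kind == "any_of":
                if not val:
                    raise ConfigError(f"pattern {self.name!r}: empty residue class")
                parts.append(f"[{re.escape(str(val))}]")
            elif kind == "literal":
                parts.append(re.escape(str(val)))
            elif kind == "gap":
                lo, hi = int(val[0]), int(val[1])
                if not (0 <= lo <= hi <= _MAX_GAP):
                    raise ConfigError(f"pattern {self.name!r}: gap bounds {val!r} out of range")
                parts.append(f".{{{lo},{hi}}}")
            elif kind == "enriched":
                residues = str(val["residues"])
                count = int(val["min_count"])
                window = int(val["window"])
                if not (1 <= count <= window <= 30):
                    raise ConfigError(f"pattern {self.name!r}: bad enriched spec {val!r}")
                cls = f"[{re.escape(residues)}]"
                # Alternation over all placements of exactly `count` fixed
                # class positions; windows with more matches are subsumed.
                alts = []
                for positions in itertools.combinations(range(window), count):
                    alts.append("".join(cls if i in positions else "." for i in range(window)))
                parts.append("(?:" + "|".join(alts) + ")")
            else:
                raise ConfigError(f"pattern {self.name!r}: unknown element kind {kind!r}")
        if not parts:
            raise ConfigError(f"pattern {self.name!r}: no elements")
        return "".join(parts)

    def to_dict(self) -> dict:
        return {"name": self.name, "elements": [dict(e) for e in self.elements]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MotifPattern":
        return cls(name=d["name"], elements=d["elements"])

    def __repr__(self) -> str:
        return f"MotifPattern({self.name!r}, {len(self.elements)} elements)"


def _c_terminal_element(gap: tuple[int, int] = (2, 5)) -> list[dict]:
    return [{"any_of": "RKH"}, {"gap": list(gap)}, {"literal": "PY"}]


def default_py_nls_patterns(linker: tuple[int, int] = (0, 30)) -> list[MotifPattern]:
    """The two shipped PY-NLS patterns (hydrophobic and basic variants)."""
    hydrophobic = MotifPattern(
        "py_nls_hydrophobic",
        [
            {"any_of": HYDROPHOBIC},
            {"any_of": "GAS"},
            {"any_of": HYDROPHOBIC},
            {"any_of": HYDROPHOBIC},
            {"gap": list(linker)},
        ]
        + _c_terminal_element(),
    )
    basic = MotifPattern(
        "py_nls_basic",
        [
            {"enriched": {"residues": "KR", "min_count": 4, "window": 6}},
            {"gap": list(linker)},
        ]
        + _c_terminal_element(),
    )
    return [hydrophobic, basic]


def sr_repeat_pattern() -> MotifPattern:
    """The SRSRSR hexapeptide marker of SR-rich splicing factors."""
    return MotifPattern("sr_repeat", [{"literal": "SRSRSR"}])


def scan(sequence: str, patterns: Sequence[MotifPattern], accession: str = "") -> list[MotifHit]:
    """Scan one sequence; report every match start, leftmost-first.

    Matches at distinct start positions are all reported (a lookahead scan),
    with the leftmost alternative taken at each start. An empty sequence
    yields no hits.
    """
    hits = []
    for pattern in patterns:
        for m in pattern._regex.finditer(sequence):
            matched = m.group(1)
            hits.append(
                MotifHit(
                    accession=accession,
                    pattern=pattern.name,
                    start=m.start() + 1,
                    end=m.start() + len(matched),
                )
            )
    hits.sort(key=lambda h: (h.pattern, h.start, h.end))
    return hits


def scan_sequences(sequences: Mapping[str, str], patterns: Sequence[MotifPattern]) -> list[MotifHit]:
    """Scan a whole sequence set; output is sorted by accession and is
    independent of the input mapping's iteration order."""
    hits = []
    for acc in sorted(sequences):
        hits.extend(scan(sequences[acc], patterns, accession=acc))
    return hits


def motif_positive(hits: Iterable[MotifHit]) -> set[str]:
    """Accessions with at least one hit for any pattern."""
    return {h.accession for h in hits}


def windowed_density(
    ranked_accessions: Sequence[str],
    positives: set[str],
    window: int = 50,
) -> list[DensityPoint]:
    """Percent motif-positive proteins in a sliding window along a ranking.

    Stride 1; the value at position 1 covers ranks 1..window. With 19 of the
    top 50 proteins motif-positive, the value at position 1 is 38.0.
    """
    n = len(ranked_accessions)
    if window < 1 or window > n:
        raise UsageError(f"window {window} out of range for a ranking of {n}")
    flags = [1 if acc in positives else 0 for acc in ranked_accessions]
    count = sum(flags[:window])
    points = [DensityPoint(position=1, pct=100.0 * count / window)]
    for pos in range(2, n - window + 2):
        count += flags[pos + window - 2] - flags[pos - 2]
        points.append(DensityPoint(position=pos, pct=100.0 * count / window))
    return points
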