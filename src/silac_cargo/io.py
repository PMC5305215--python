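"""Readers and writers for the tabular and sequence formats the pipeline touches.

All tables are tab-separated with named header columns. Quantification tables
are protein-level exports from a search engine: one row per protein with a
light/heavy (L/H) SILAC ratio and the number of quantified peptide-ratio
events (the L/H count). Proteins with an L/H count of zero, or with a missing
ratio, carry no usable quantification and are dropped on read.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import DataError, FormatError

__all__ = [
    "Condition",
    "Localization",
    "QuantRecord",
    "QuantRun",
    "AnnotationSet",
    "read_quant_table",
    "write_quant_table",
    "read_annotations",
    "read_fasta",
    "write_ranking",
    "read_ranking",
    "write_evaluation",
    "read_evaluation",
    "write_manifest",
]


class Condition(str, enum.Enum):
    """Run condition: receptor added (+NTR) or receptor-free control."""

    CTL = "ctl"
    NTR = "ntr"


class Localization(str, enum.Enum):
    """UniProt-style subcellular localization class used for negative examples."""

    NUCLEAR = "nuclear"
    NON_NUCLEAR = "non_nuclear"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class QuantRecord:
    """One protein's quantification in one run."""

    lh_ratio: float
    lh_count: int


@dataclass
class QuantRun:
    """One mass-spec run's protein-level SILAC quantification.

    Parameters
    ----------
    receptor
        Transport-receptor name (e.g. ``"Trn-1"``) or ``None`` for a control run.
    condition
        :class:`Condition` (``ctl`` or ``ntr``).
    replicate
        1-based replicate index.
    records
        Mapping accession -> :class:`QuantRecord`. Accessions are unique by
        construction of the mapping; every ratio must be finite and positive.
    """

    receptor: str | None
    condition: Condition
    replicate: int
    records: dict[str, QuantRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        if self.condition is Condition.NTR and not self.receptor:
            raise DataError("a +NTR run requires a non-empty receptor name")
        for acc, rec in self.records.items():
            if not (math.isfinite(rec.lh_ratio) and rec.lh_ratio > 0):
                raise DataError(f"non-positive or non-finite L/H ratio for {acc!r}")
            if rec.lh_count < 0:
                raise DataError(f"negative L/H count for {acc!r}")

    def __len__(self) -> int:
        return len(self.records)

    def accessions(self) -> set[str]:
        return set(self.records)


@dataclass
class AnnotationSet:
    """Reported-cargo and localization annotation.

    ``reported`` maps receptor name to the set of previously reported cargo
    accessions; sets may overlap between receptors. ``localization`` maps an
    accession to its localization class; accessions absent from the mapping
    are treated as undetermined.
    """

    reported: dict[str, set[str]] = field(default_factory=dict)
    localization: dict[str, Localization] = field(default_factory=dict)

    def localization_of(self, accession: str) -> Localization:
        return self.localization.get(accession, Localization.UNDETERMINED)


_DEFAULT_QUANT_COLUMNS = {
    "accession": "accession",
    "lh_ratio": "lh_ratio",
    "lh_count": "lh_count",
}


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except FileNotFoundError:
        raise
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc


def read_quant_table(
    path: str | Path,
    receptor: str | None,
    condition: Condition | str,
    replicate: int,
    columns: Mapping[str, str] | None = None,
    min_count: int = 1,
) -> QuantRun:
    """Read a protein-level quantification TSV into a :class:`QuantRun`.

    ``columns`` optionally remaps the logical column names (``accession``,
    ``lh_ratio``, ``lh_count``) onto the header names actually present, so
    differently labelled search-engine exports can be read without editing
    the file. Rows with an L/H count below ``min_count`` (default 1: at
    least one quantified peptide-ratio event) or a missing ratio are
    dropped; a duplicate accession among the retained rows is a data error.
    """
    colmap = dict(_DEFAULT_QUANT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = _read_tsv(path)
    for logical, name in colmap.items():
        if name not in df.columns:
            raise FormatError(f"{path}: missing required column {name!r} ({logical})")
    records: dict[str, QuantRecord] = {}
    for _, row in df.iterrows():
        raw_ratio = row[colmap["lh_ratio"]]
        raw_count = row[colmap["lh_count"]]
        count = int(float(raw_count)) if pd.notna(raw_count) else 0
        if count < max(1, min_count) or pd.isna(raw_ratio):
            continue
        acc = str(row[colmap["accession"]])
        ratio = float(raw_ratio)
        if not (math.isfinite(ratio) and ratio > 0):
            raise DataError(f"{path}: non-positive L/H ratio {ratio!r} for accession {acc!r}")
        if acc in records:
            raise DataError(f"{path}: duplicate accession {acc!r}")
        records[acc] = QuantRecord(lh_ratio=ratio, lh_count=count)
    return QuantRun(receptor=receptor, condition=Condition(condition), replicate=replicate, records=records)


def write_quant_table(run: QuantRun, path: str | Path) -> None:
    """Write a :class:`QuantRun` as a TSV readable by :func:`read_quant_table`."""
    with open(path, "w") as fh:
        fh.write("accession\tlh_ratio\tlh_count\n")
        for acc in sorted(run.records):
            rec = run.records[acc]
            fh.write(f"{acc}\t{rec.lh_ratio!r}\t{rec.lh_count}\n")


def read_annotations(reported_path: str | Path, localization_path: str | Path) -> AnnotationSet:
    """Read reported-cargo and localization TSVs.

    The reported table has columns ``receptor`` and ``accession``; the
    localization table has columns ``accession`` and ``class``. Unknown class
    strings map to :attr:`Localization.UNDETERMINED`.
    """
    reported_df = _read_tsv(reported_path)
    for col in ("receptor", "accession"):
        if col not in reported_df.columns:
            raise FormatError(f"{reported_path}: missing required column {col!r}")
    loc_df = _read_tsv(localization_path)
    for col in ("accession", "class"):
        if col not in loc_df.columns:
            raise FormatError(f"{localization_path}: missing required column {col!r}")

    reported: dict[str, set[str]] = {}
    for _, row in reported_df.iterrows():
        reported.setdefault(str(row["receptor"]), set()).add(str(row["accession"]))
    localization: dict[str, Localization] = {}
    for _, row in loc_df.iterrows():
        try:
            cls = Localization(str(row["class"]))
        except ValueError:
            cls = Localization.UNDETERMINED
        localization[str(row["accession"])] = cls
    return AnnotationSet(reported=reported, localization=localization)


_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XUBZ")
_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{accession: sequence}``.

    The accession is the first whitespace-delimited header token; for UniProt
    ``sp|ACC|NAME`` headers the middle field is used. Sequences are
    upper-cased and ``*`` terminators stripped; the 20 standard residues plus
    X, U, B, Z are accepted.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: sequence data before first FASTA header")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        token = record.id
        m = _UNIPROT_HEADER.match(token)
        acc = m.group(1) if m else token
        seq = str(record.seq).upper().rstrip("*")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise FormatError(f"{path}: invalid residue(s) {sorted(bad)} in {acc!r}")
        if acc in sequences:
            raise FormatError(f"{path}: duplicate accession {acc!r}")
        sequences[acc] = seq
    return sequences


_RANKING_COLUMNS = ["rank", "accession", "statistic", "z1", "z2", "z3", "n_values", "percentile"]


def write_ranking(entries: Sequence, path: str | Path) -> None:
    """Write a ranked protein list as TSV.

    ``entries`` are :class:`~silac_cargo.ranking.RankedProtein` rows (or any
    object with the same attributes). Column order is fixed and named in the
    header: rank, accession, statistic, z1..z3, n_values, percentile. Floats
    are serialized with ``repr`` so a read round-trips exactly.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_RANKING_COLUMNS) + "\n")
        for e in entries:
            zs = list(e.z_values) + [None] * (3 - len(e.z_values))
            zcols = ["NA" if z is None else repr(float(z)) for z in zs]
            fh.write(
                f"{e.rank}\t{e.accession}\t{float(e.statistic)!r}\t"
                + "\t".join(zcols)
                + f"\t{e.n_values}\t{float(e.percentile)!r}\n"
            )


def read_ranking(path: str | Path) -> list["RankedRow"]:
    """Read a ranking TSV written by :func:`write_ranking`."""
    df = _read_tsv(path)
    for col in _RANKING_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rows = []
    for _, r in df.iterrows():
        zs = tuple(float(r[c]) for c in ("z1", "z2", "z3") if pd.notna(r[c]) and r[c] != "NA")
        rows.append(
            RankedRow(
                rank=int(r["rank"]),
                accession=str(r["accession"]),
                statistic=float(r["statistic"]),
                z_values=zs,
                n_values=int(r["n_values"]),
                percentile=float(r["percentile"]),
            )
        )
    return rows


@dataclass(frozen=True)
class RankedRow:
    """One row of a serialized ranking (mirror of RankedProtein for round-trips)."""

    rank: int
    accession: str
    statistic: float
    z_values: tuple[float, ...]
    n_values: int
    percentile: float


_EVAL_COLUMNS = [
    "cutoff_pct", "n_top", "p_i", "n_i", "P_total", "N_eval", "rate", "recall", "fisher_p",
]


def write_evaluation(points: Iterable, path: str | Path) -> None:
    """Write a cutoff-sweep evaluation as TSV.

    p-values are serialized in scientific notation with four significant
    digits; an undefined rate (no positives or negatives in the slice) is
    written as ``NA``.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_EVAL_COLUMNS) + "\n")
        for p in points:
            rate = "NA" if p.rate is None else f"{p.rate:.6f}"
            fh.write(
                f"{p.cutoff_pct}\t{p.n_top}\t{p.p_i}\t{p.n_i}\t{p.P_total}\t{p.N_eval}\t"
                f"{rate}\t{p.recall:.6f}\t{p.fisher_p:.3e}\n"
            )


def read_evaluation(path: str | Path) -> pd.DataFrame:
    """Read an evaluation TSV back as a DataFrame (``rate`` may contain NaN)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in _EVAL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def write_manifest(path: str | Path, payload: Mapping) -> None:
    """Write a run manifest (inputs, parameters, seed) as JSON."""
    with open(path, "w") as fh:
        json.dump(dict(payload), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
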