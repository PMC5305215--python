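"""Ratio-of-ratios import index and per-replicate Z-scores.

The import index of a protein is +NTR/Ctl = (L/H_+NTR)/(L/H_Ctl): the
light/heavy SILAC ratio measured with the transport receptor present divided
by the ratio from the receptor-free control of the same replicate. A protein
must be quantified in both runs; unpaired measurements are discarded. The
index is analysed on the log2 scale, X = log2(+NTR/Ctl), and standardized
within each replicate as Z = (X - mu) / sigma, where mu and sigma are the
mean and standard deviation of X over all paired proteins of that replicate.
The sample (n-1) standard deviation is used; with thousands of proteins per
replicate the convention is numerically negligible but it is fixed here for
reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, DomainError, UsageError
from .io import Condition, QuantRun

__all__ = ["RatioRecord", "pair_ratios", "log2_index", "zscore_within_replicate", "ratio_records"]


@dataclass(frozen=True)
class RatioRecord:
    """A protein's paired ratios and derived statistics in one replicate."""

    accession: str
    replicate: int
    lh_ntr: float
    lh_ctl: float
    index: float   # +NTR/Ctl
    x: float       # log2(index)
    z: float       # Z-score of x within the replicate


def pair_ratios(ntr_run: QuantRun, ctl_run: QuantRun) -> list[tuple[str, float, float]]:
    """Pair +NTR and control L/H ratios of the same replicate.

    Returns ``(accession, lh_ntr, lh_ctl)`` for exactly the accessions
    quantified in both runs, sorted by accession. Proteins quantified in only
    one of the two runs are discarded: the import index is undefined without
    its counterpart.
    """
    if ntr_run.replicate != ctl_run.replicate:
        raise UsageError(
            f"replicate mismatch: +NTR run is replicate {ntr_run.replicate}, "
            f"control is replicate {ctl_run.replicate}"
        )
    if ntr_run.condition is not Condition.NTR or ctl_run.condition is not Condition.CTL:
        raise UsageError("pair_ratios expects a (+NTR, control) run pair in that order")
    shared = ntr_run.accessions() & ctl_run.accessions()
    return [
        (acc, ntr_run.records[acc].lh_ratio, ctl_run.records[acc].lh_ratio)
        for acc in sorted(shared)
    ]


def log2_index(lh_ntr: float, lh_ctl: float) -> tuple[float, float]:
    """Compute the import index +NTR/Ctl and its log2, X."""
    if not (lh_ntr > 0 and lh_ctl > 0):
        raise DomainError(f"L/H ratios must be positive, got ({lh_ntr}, {lh_ctl})")
    index = lh_ntr / lh_ctl
    return index, math.log2(index)


def zscore_within_replicate(xs: Sequence[float]) -> list[float]:
    """Standardize a replicate's X values: Z = (X - mean) / sd (sample sd).

    Requires at least two values and non-zero spread. The output has mean 0
    and sample sd 1 to within numerical precision.
    """
    if len(xs) < 2:
        raise UsageError(f"need at least 2 values to standardize, got {len(xs)}")
    arr = np.asarray(xs, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("all X values identical: standard deviation is zero")
    return list((arr - arr.mean()) / sd)


def ratio_records(ntr_run: QuantRun, ctl_run: QuantRun) -> list[RatioRecord]:
    """Full per-replicate table: pair, compute indices, standardize.

    Z-scores are computed over all paired proteins of the replicate.
    """
    pairs = pair_ratios(ntr_run, ctl_run)
    if len(pairs) < 2:
        raise UsageError("fewer than 2 paired proteins; cannot standardize this replicate")
    indexed = [(acc, a, b, *log2_index(a, b)) for acc, a, b in pairs]
    zs = zscore_within_replicate([row[4] for row in indexed])
    return [
        RatioRecord(
            accession=acc,
            replicate=ntr_run.replicate,
            lh_ntr=a,
            lh_ctl=b,
            index=idx,
            x=x,
            z=z,
        )
        for (acc, a, b, idx, x), z in zip(indexed, zs)
    ]
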