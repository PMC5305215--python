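"""Convenience drivers that chain the pipeline stages.

These helpers wire quantification runs through pairing, Z-scoring,
order-statistic aggregation, and ranking for one receptor, and are used by
the command-line interface, the test suite, and the acceptance script.
"""

from __future__ import annotations

from typing import Sequence

from .errors import UsageError
from .io import Condition, QuantRun
from .ranking import (
    Criterion,
    RankedProtein,
    RankingEntry,
    Statistic,
    assemble,
    call_cargo_set,
    rank_proteins,
)
from .ratio import ratio_records

__all__ = ["rankings_for_receptor", "cargo_sets_for_receptor"]


def rankings_for_receptor(
    runs: Sequence[QuantRun], receptor: str
) -> tuple[list[RankedProtein], list[RankedProtein]]:
    """Build the 2nd-Z and 3rd-Z rankings for one receptor.

    ``runs`` must contain the receptor's +NTR runs and, for each of their
    replicates, a control run (receptor-specific control if present,
    otherwise a shared control with receptor ``None``).
    """
    ntr_runs = {
        r.replicate: r for r in runs if r.condition is Condition.NTR and r.receptor == receptor
    }
    if not ntr_runs:
        raise UsageError(f"no +NTR runs for receptor {receptor!r}")
    tables = {}
    for replicate, ntr in sorted(ntr_runs.items()):
        ctls = [
            r
            for r in runs
            if r.condition is Condition.CTL
            and r.replicate == replicate
            and r.receptor in (receptor, None)
        ]
        if not ctls:
            raise UsageError(f"no control run for replicate {replicate} of {receptor!r}")
        tables[replicate] = ratio_records(ntr, ctls[0])
    entries = assemble(tables)
    second = rank_proteins(entries, Statistic.SECOND_Z)
    triple = [e for e in entries if e.n_values == 3]
    third = rank_proteins(triple, Statistic.THIRD_Z) if len(triple) >= 1 else []
    return second, third


def cargo_sets_for_receptor(runs: Sequence[QuantRun], receptor: str):
    """Call the high-sensitivity (2nd-Z-15%) and high-specificity (3rd-Z-4%)
    cargo sets for one receptor; the latter is ``None`` when no protein was
    quantified in all replicates."""
    second, third = rankings_for_receptor(runs, receptor)
    sens = call_cargo_set(second, receptor, Criterion.SECOND_Z_15)
    spec = call_cargo_set(third, receptor, Criterion.THIRD_Z_4) if third else None
    return sens, spec
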