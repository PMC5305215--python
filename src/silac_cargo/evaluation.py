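"""Calibration of rankings against reported-cargo annotation.

At each percentile cutoff i the top slice of a ranking is scored against the
previously reported cargoes of the receptor:

    reported cargo rate(i) = p(i) / [p(i) + n(i)]
    recall(i)              = p(i) / P

where p(i) is the number of reported cargoes in the top i%, n(i) the number
of negative examples there, and P the total number of reported cargoes in
the ranking. Because no gold-standard negative set exists, two negative
definitions are supported: (i) every unreported protein is negative (the
rate is then a lower bound on precision), and (ii) only unreported proteins
annotated with non-nuclear localization are negative, the rest being
excluded from the evaluation universe entirely.

Enrichment significance is the one-sided Fisher exact test, i.e. the upper
tail of the hypergeometric distribution, computed in log-space.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import DomainError, UsageError
from .io import AnnotationSet, Localization
from .ranking import RankedProtein, cutoff_count

__all__ = [
    "NegativeDefinition",
    "EvaluationPoint",
    "fisher_enrichment_p",
    "rate_and_recall",
    "evaluate_cutoffs",
]


class NegativeDefinition(str, enum.Enum):
    ALL_UNREPORTED = "all_unreported"
    NON_NUCLEAR_ONLY = "non_nuclear_only"


@dataclass(frozen=True)
class EvaluationPoint:
    """Counts and statistics of one percentile cutoff."""

    cutoff_pct: int
    n_top: int        # proteins in the top i% of the full ranking
    p_i: int          # reported cargoes in the top i%
    n_i: int          # negative examples in the top i%
    P_total: int      # reported cargoes in the whole ranking
    N_eval: int       # positives + negatives in the evaluation universe
    rate: float | None
    recall: float
    fisher_p: float


def _log_comb(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(np.asarray(a) - b + 1)


def fisher_enrichment_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), X ~ Hypergeom(N, K, n).

    Equivalent to the one-sided (enrichment) Fisher exact p-value of the 2x2
    table [[k, n-k], [K-k, N-n-K+k]]: drawing ``n`` proteins from ``N`` of
    which ``K`` are positives, the probability of seeing ``k`` or more
    positives. Summed in log-space via log-gamma for numerical stability.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"need 0 <= K <= N and 0 <= n <= N, got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise DomainError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    js = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, js) + _log_comb(N - K, n - js) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def rate_and_recall(p_i: int, n_i: int, P_total: int) -> tuple[float | None, float]:
    """Reported cargo rate and recall from slice counts.

    The rate is ``None`` (undefined, not zero) when the slice contains
    neither positives nor negatives.
    """
    if P_total < 1:
        raise UsageError("P_total must be >= 1: recall is undefined without positives")
    if p_i > P_total:
        raise DomainError(f"p_i={p_i} exceeds P_total={P_total}")
    rate = p_i / (p_i + n_i) if (p_i + n_i) > 0 else None
    return rate, p_i / P_total


def evaluate_cutoffs(
    ranking: Sequence[RankedProtein],
    annotations: AnnotationSet,
    receptor: str,
    neg_def: NegativeDefinition | str = NegativeDefinition.ALL_UNREPORTED,
    increments: int = 1,
    max_pct: int = 100,
) -> list[EvaluationPoint]:
    """Sweep percentile cutoffs and score each against reported cargoes.

    Cutoff slices are taken on the full ranking first; under the non-nuclear
    negative definition, excluded proteins (unreported, with nuclear or
    undetermined localization) are then removed from both the slice counts
    and the totals before computing the rate and the Fisher p-value. Recall
    always uses the full positive count P of the ranking.
    """
    neg_def = NegativeDefinition(neg_def)
    if not ranking:
        raise UsageError("ranking is empty")
    if increments < 1 or max_pct < increments or max_pct > 100:
        raise UsageError(f"bad sweep: increments={increments}, max_pct={max_pct}")
    ordered = [r.accession for r in ranking]
    in_ranking = set(ordered)
    positives = annotations.reported.get(receptor, set()) & in_ranking
    if not positives:
        raise UsageError(f"no reported cargo of {receptor!r} is present in the ranking")
    if neg_def is NegativeDefinition.ALL_UNREPORTED:
        negatives = in_ranking - positives
    else:
        negatives = {
            acc
            for acc in in_ranking - positives
            if annotations.localization_of(acc) is Localization.NON_NUCLEAR
        }
    P_total = len(positives)
    N_eval = P_total + len(negatives)
    n_ranked = len(ordered)
    points = []
    for pct in range(increments, max_pct + 1, increments):
        n_top = cutoff_count(n_ranked, pct)
        top = ordered[:n_top]
        p_i = sum(1 for acc in top if acc in positives)
        n_i = sum(1 for acc in top if acc in negatives)
        rate, recall = rate_and_recall(p_i, n_i, P_total)
        fisher_p = fisher_enrichment_p(p_i, P_total, p_i + n_i, N_eval)
        points.append(
            EvaluationPoint(
                cutoff_pct=pct,
                n_top=n_top,
                p_i=p_i,
                n_i=n_i,
                P_total=P_total,
                N_eval=N_eval,
                rate=rate,
                recall=recall,
                fisher_p=fisher_p,
            )
        )
    return points
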