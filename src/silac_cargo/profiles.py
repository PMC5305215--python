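"""Cross-receptor cargo-profile comparison.

Called cargo sets are compared by set algebra (pairwise sharing counts,
per-receptor unique cargoes) and as binary membership profiles: a receptors
x cargo-universe 0/1 matrix whose rows are clustered agglomeratively with
Ward linkage on Euclidean distances. Two Ward dialects are provided because
R's historical ``hclust`` offers both: the default operates on squared
Euclidean distances with merge heights reported on the distance scale
(``ward.D2`` semantics); the alternative applies the same Lance-Williams
update to unsquared distances (``ward.D``). The agglomeration tie-break is
the lexicographically smallest cluster-id pair among minimal-distance pairs,
so output is byte-stable. Dendrograms export to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import UsageError
from .ranking import CargoSet

__all__ = [
    "ProfileMatrix",
    "SharingSummary",
    "Dendrogram",
    "sharing_summary",
    "build_profile_matrix",
    "ward_cluster",
    "to_newick",
]


@dataclass(frozen=True)
class ProfileMatrix:
    """Binary receptors x cargo-universe membership matrix."""

    receptors: tuple[str, ...]
    universe: tuple[str, ...]  # sorted union of all members
    matrix: np.ndarray         # shape (len(receptors), len(universe)), dtype int8


@dataclass(frozen=True)
class SharingSummary:
    receptors: tuple[str, ...]
    pairwise: np.ndarray          # symmetric shared-cargo counts; diagonal = set sizes
    unique_counts: tuple[int, ...]  # cargoes belonging to exactly one receptor
    total_cargoes: int
    mean_pairwise: float


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree in linkage-matrix form.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height, size),
    with original observations numbered 0..n-1 and merge i creating cluster
    n+i, as in scipy's linkage matrices.
    """

    labels: tuple[str, ...]
    merges: np.ndarray  # shape (n-1, 4)


def _check_sets(cargo_sets: Sequence[CargoSet]) -> None:
    if len(cargo_sets) < 2:
        raise UsageError(f"need at least 2 cargo sets, got {len(cargo_sets)}")
    names = [cs.receptor for cs in cargo_sets]
    if len(set(names)) != len(names):
        raise UsageError(f"duplicate receptor names in {names}")
    for cs in cargo_sets:
        if not cs.members:
            raise UsageError(f"cargo set for {cs.receptor!r} is empty")


def sharing_summary(cargo_sets: Sequence[CargoSet]) -> SharingSummary:
    """Pairwise sharing counts, per-receptor unique cargoes, and totals."""
    _check_sets(cargo_sets)
    sets = [set(cs.members) for cs in cargo_sets]
    names = tuple(cs.receptor for cs in cargo_sets)
    m = len(sets)
    pairwise = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(m):
            pairwise[i, j] = len(sets[i] & sets[j])
    universe = set().union(*sets)
    membership = {acc: sum(acc in s for s in sets) for acc in universe}
    unique_counts = tuple(sum(1 for acc in s if membership[acc] == 1) for s in sets)
    off_diag = [pairwise[i, j] for i in range(m) for j in range(i + 1, m)]
    return SharingSummary(
        receptors=names,
        pairwise=pairwise,
        unique_counts=unique_counts,
        total_cargoes=len(universe),
        mean_pairwise=float(np.mean(off_diag)),
    )


def build_profile_matrix(cargo_sets: Sequence[CargoSet]) -> ProfileMatrix:
    """Binary membership matrix: rows in input receptor order, columns the
    lexicographically sorted union of all members."""
    _check_sets(cargo_sets)
    universe = tuple(sorted(set().union(*(set(cs.members) for cs in cargo_sets))))
    col = {acc: j for j, acc in enumerate(universe)}
    matrix = np.zeros((len(cargo_sets), len(universe)), dtype=np.int8)
    for i, cs in enumerate(cargo_sets):
        for acc in cs.members:
            matrix[i, col[acc]] = 1
    return ProfileMatrix(
        receptors=tuple(cs.receptor for cs in cargo_sets),
        universe=universe,
        matrix=matrix,
    )


def ward_cluster(profile: ProfileMatrix, dialect: str = "ward.D2") -> Dendrogram:
    """Agglomerative Ward clustering of the profile rows.

    Lance-Williams recurrence
        d(k, i+j)^2 = [(n_i+n_k) d(k,i)^2 + (n_j+n_k) d(k,j)^2 - n_k d(i,j)^2]
                      / (n_i + n_j + n_k)
    applied to squared Euclidean distances (``ward.D2``, default; heights are
    reported as sqrt of the merged squared distance, matching scipy/R
    ward.D2) or to unsquared distances (``ward.D``).
    """
    if dialect not in ("ward.D2", "ward.D"):
        raise UsageError(f"unknown Ward dialect {dialect!r}")
    x = np.asarray(profile.matrix, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise UsageError("need at least 2 rows to cluster")
    d = squareform(pdist(x, metric="euclidean"))
    work = d**2 if dialect == "ward.D2" else d.copy()

    # active clusters: id -> (work-matrix row, size)
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    index = {i: i for i in range(n)}  # cluster id -> row in `work`
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                val = work[index[a], index[b]]
                key = (val, a, b)
                if best is None or key < best:
                    best = key
        val, a, b = best
        height = float(np.sqrt(val)) if dialect == "ward.D2" else float(val)
        na, nb = size[a], size[b]
        merges[step] = (a, b, height, na + nb)
        # Lance-Williams update into row of `a`; retire `b`.
        ra, rb = index[a], index[b]
        for c in active:
            if c in (a, b):
                continue
            rc, nc = index[c], size[c]
            new = ((na + nc) * work[ra, rc] + (nb + nc) * work[rb, rc] - nc * work[ra, rb]) / (
                na + nb + nc
            )
            work[ra, rc] = work[rc, ra] = new
        active.remove(b)
        active.remove(a)
        active.append(next_id)
        index[next_id] = ra
        size[next_id] = na + nb
        next_id += 1
    return Dendrogram(labels=profile.receptors, merges=merges)


def to_newick(dendrogram: Dendrogram, precision: int = 6) -> str:
    """Serialize a dendrogram as Newick; branch lengths are height differences."""
    n = len(dendrogram.labels)
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, (a, b, h, _) in enumerate(dendrogram.merges):
        node = n + step
        height[node] = float(h)
        children[node] = (int(a), int(b))

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height[node]
        if node < n:
            return f"{dendrogram.labels[node]}:{length:.{precision}g}"
        a, b = children[node]
        inner = ",".join(render(c, height[node]) for c in (a, b))
        return f"({inner}):{length:.{precision}g}"

    root = n + len(children) - 1
    a, b = children[root]
    inner = ",".join(render(c, height[root]) for c in (a, b))
    return f"({inner});"
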