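import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist

from silac_cargo.errors import UsageError
from silac_cargo.profiles import (
    ProfileMatrix,
    build_profile_matrix,
    sharing_summary,
    to_newick,
    ward_cluster,
)
from silac_cargo.ranking import CargoSet, Criterion


def cargo_set(receptor, members):
    return CargoSet(receptor=receptor, criterion=Criterion.THIRD_Z_4, members=tuple(members))


class TestSharingSummary:
    def test_hand_counted_example(self):
        s = sharing_summary([cargo_set("R1", "ABC"), cargo_set("R2", "BCD")])
        assert s.pairwise[0, 1] == 2
        assert s.unique_counts == (1, 1)
        assert s.total_cargoes == 4
        assert s.mean_pairwise == 2.0

    def test_identical_sets(self):
        s = sharing_summary([cargo_set("R1", "ABC"), cargo_set("R2", "ABC")])
        assert s.pairwise[0, 1] == 3 and s.unique_counts == (0, 0)

    def test_duplicate_receptor_rejected(self):
        with pytest.raises(UsageError):
            sharing_summary([cargo_set("R1", "AB"), cargo_set("R1", "BC")])

    def test_unique_plus_shared_equals_size(self):
        rng = np.random.default_rng(3)
        sets = [cargo_set(f"R{i}", {f"c{j}" for j in rng.choice(60, 15, replace=False)})
                for i in range(6)]
        s = sharing_summary(sets)
        for i, cs in enumerate(sets):
            members = set(cs.members)
            others = set().union(*(set(o.members) for j, o in enumerate(sets) if j != i))
            shared = len(members & others)
            assert s.unique_counts[i] + shared == len(members)

    def test_matches_bruteforce_oracle_on_random_sets(self):
        rng = np.random.default_rng(11)
        sets = [cargo_set(f"R{i:02d}", {f"c{j}" for j in rng.choice(200, 25, replace=False)})
                for i in range(12)]
        s = sharing_summary(sets)
        raw = [set(cs.members) for cs in sets]
        for i in range(12):
            for j in range(12):
                assert s.pairwise[i, j] == len(raw[i] & raw[j])
        universe = set().union(*raw)
        assert s.total_cargoes == len(universe)
        uniques = [sum(1 for c in raw[i] if sum(c in r for r in raw) == 1) for i in range(12)]
        assert list(s.unique_counts) == uniques
        offdiag = [len(raw[i] & raw[j]) for i in range(12) for j in range(i + 1, 12)]
        assert s.mean_pairwise == pytest.approx(np.mean(offdiag))


class TestProfileMatrix:
    def test_shared_column_sums(self):
        pm = build_profile_matrix([cargo_set("R1", ["x", "a"]), cargo_set("R2", ["x", "b"])])
        assert pm.universe == ("a", "b", "x")
        assert list(pm.matrix.sum(axis=0)) == [1, 1, 2]

    def test_disjoint_sets_column_sums_one(self):
        pm = build_profile_matrix([cargo_set("R1", "AB"), cargo_set("R2", "CD")])
        assert all(pm.matrix.sum(axis=0) == 1)
        assert all(pm.matrix.sum(axis=1) >= 1)

    def test_universe_is_union(self):
        sets = [cargo_set("R1", "ABC"), cargo_set("R2", "BCD"), cargo_set("R3", "E")]
        pm = build_profile_matrix(sets)
        assert set(pm.universe) == set("ABCDE")


def random_profile(n_rows, n_cols, seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(0, 2, size=(n_rows, n_cols)).astype(np.int8)
    m[m.sum(axis=1) == 0, 0] = 1  # every row non-empty
    return ProfileMatrix(
        receptors=tuple(f"R{i:02d}" for i in range(n_rows)),
        universe=tuple(f"c{j:03d}" for j in range(n_cols)),
        matrix=m,
    )


class TestWardCluster:
    def test_identical_rows_merge_first_at_zero(self):
        m = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=np.int8)
        pm = ProfileMatrix(("A", "B", "C"), ("w", "x", "y", "z"), m)
        tree = ward_cluster(pm)
        first = tree.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0

    def test_planted_overlap_pair_are_siblings(self):
        """Receptors sharing 90% of their cargoes pair before anything else."""
        rng = np.random.default_rng(5)
        universe = [f"c{j}" for j in range(120)]
        base = list(rng.choice(universe, 20, replace=False))
        r1 = set(base)
        r2 = set(base[:18]) | set(rng.choice([u for u in universe if u not in base], 2, False))
        others = [set(rng.choice(universe, 20, replace=False)) for _ in range(4)]
        sets = [cargo_set("R1", r1), cargo_set("R2", r2)] + [
            cargo_set(f"O{i}", s) for i, s in enumerate(others)
        ]
        tree = ward_cluster(build_profile_matrix(sets))
        first = tree.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_heights_non_decreasing(self):
        for seed in range(4):
            tree = ward_cluster(random_profile(8, 40, seed))
            heights = tree.merges[:, 2]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_scipy_ward_on_generic_data(self):
        """Cross-check the Lance-Williams implementation against scipy's ward
        linkage via cophenetic distances (tie-free float data)."""
        rng = np.random.default_rng(17)
        x = rng.normal(size=(9, 5))
        pm = ProfileMatrix(tuple(f"R{i}" for i in range(9)), tuple("abcde"), x)
        ours = ward_cluster(pm, dialect="ward.D2")
        ref = linkage(x, method="ward")
        assert np.allclose(np.sort(ours.merges[:, 2]), np.sort(ref[:, 2]))
        assert np.allclose(cophenet(ours.merges), cophenet(ref))

    def test_ward_d_dialect_heights_differ_but_small_trees_agree(self):
        pm = random_profile(6, 30, 2)
        d2 = ward_cluster(pm, dialect="ward.D2")
        d1 = ward_cluster(pm, dialect="ward.D")
        assert d1.merges.shape == d2.merges.shape
        assert not np.allclose(d1.merges[:, 2], d2.merges[:, 2])

    def test_column_order_invariance(self):
        pm = random_profile(7, 30, 9)
        rng = np.random.default_rng(1)
        perm = rng.permutation(30)
        shuffled = ProfileMatrix(pm.receptors,
                                 tuple(pm.universe[j] for j in perm),
                                 pm.matrix[:, perm])
        a, b = ward_cluster(pm), ward_cluster(shuffled)
        assert np.allclose(a.merges, b.merges)

    def test_three_leaf_sibling_is_closest_pair(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=(3, 6))
        pm = ProfileMatrix(("A", "B", "C"), tuple("uvwxyz"), x)
        tree = ward_cluster(pm)
        d = pdist(x)
        pairs = [(0, 1), (0, 2), (1, 2)]
        closest = set(pairs[int(np.argmin(d))])
        assert {int(tree.merges[0, 0]), int(tree.merges[0, 1])} == closest

    def test_single_row_rejected(self):
        pm = ProfileMatrix(("A",), ("x",), np.array([[1]], dtype=np.int8))
        with pytest.raises(UsageError):
            ward_cluster(pm)


class TestNewick:
    def test_two_leaf_shape(self):
        pm = ProfileMatrix(("A", "B"), ("x", "y"),
                           np.array([[1, 0], [0, 1]], dtype=np.int8))
        tree = ward_cluster(pm)
        nwk = to_newick(tree)
        h = tree.merges[0, 2]
        assert nwk == f"(A:{h:.6g},B:{h:.6g});"

    def test_round_trip_topology(self):
        import dendropy

        pm = random_profile(7, 25, 4)
        tree = ward_cluster(pm)
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(pm.receptors)
        # sibling structure of the first merge survives serialization
        a, b = int(tree.merges[0, 0]), int(tree.merges[0, 1])
        la, lb = pm.receptors[a], pm.receptors[b]
        node = parsed.mrca(taxon_labels=[la, lb])
        assert {leaf.taxon.label for leaf in node.leaf_iter()} == {la, lb}

    def test_root_ward_heights_increase(self):
        for seed in range(3):
            pm = random_profile(6, 20, seed + 40)
            tree = ward_cluster(pm)
            n = len(pm.receptors)
            height = {i: 0.0 for i in range(n)}
            for step, (a, b, h, _) in enumerate(tree.merges):
                node = n + step
                height[node] = h
                assert h >= height[int(a)] - 1e-12 and h >= height[int(b)] - 1e-12
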