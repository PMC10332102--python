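"""Alignment, distance, NJ, bootstrap and clan-assignment behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from familyscope.io_formats import PROTEIN, SequenceSet
from familyscope.phylogeny import (
    GAP_EXTEND,
    GAP_OPEN,
    _B62,
    _AA_INDEX,
    DistanceMatrix,
    Msa,
    PhyloTree,
    TreeNode,
    assign_clans,
    bootstrap_support,
    compute_distances,
    nj_tree,
    pairwise_align,
    pairwise_align_score,
    progressive_align,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def enumerate_alignment_scores(a: str, b: str):
    """Brute-force oracle: enumerate every global alignment, affine-scored."""

    best = [-np.inf]

    def step(i, j, score, prev):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = _B62[_AA_INDEX[a[i]], _AA_INDEX[b[j]]]
            step(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = GAP_EXTEND if prev == "X" else GAP_OPEN
            step(i + 1, j, score + cost, "X")
        if j < len(b):
            cost = GAP_EXTEND if prev == "Y" else GAP_OPEN
            step(i, j + 1, score + cost, "Y")

    step(0, 0, 0.0, None)
    return best[0]


class TestAlignment:
    def test_identical_sequences_align_gapless(self):
        row_a, row_b = pairwise_align("MKVLLAT", "MKVLLAT")
        assert row_a == row_b == "MKVLLAT"

    def test_single_deletion_example_matches_exhaustive_oracle(self):
        row_a, row_b = pairwise_align("ACDE", "ACE")
        assert len(row_a) == 4
        assert row_b.count("-") == 1
        assert pairwise_align_score("ACDE", "ACE") == pytest.approx(
            enumerate_alignment_scores("ACDE", "ACE")
        )

    @pytest.mark.parametrize("pair", [("MKFG", "MKG"), ("ACDEFG", "ADFG"), ("WW", "WAW")])
    def test_pairwise_score_equals_oracle_on_small_inputs(self, pair):
        assert pairwise_align_score(*pair) == pytest.approx(
            enumerate_alignment_scores(*pair)
        )

    def test_ungapping_recovers_inputs_on_fifty_proteins(self):
        rng = np.random.default_rng(4)
        seqs = [
            (f"s{i}", "".join(AA[k] for k in rng.integers(0, 20, rng.integers(30, 61))))
            for i in range(50)
        ]
        msa = progressive_align(seqs)
        originals = dict(seqs)
        for idx, gene_id in enumerate(msa.ids):
            assert msa.ungapped(idx) == originals[gene_id]

    def test_single_sequence_returned_as_trivial_msa(self):
        msa = progressive_align([("only", "MKV")])
        assert msa.rows == ["MKV"]


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    st.lists(
        st.text(alphabet=AA, min_size=5, max_size=30), min_size=2, max_size=5
    )
)
def test_progressive_alignment_preserves_every_input_sequence(seqs):
    records = [(f"s{i}", s) for i, s in enumerate(seqs)]
    msa = progressive_align(records)
    originals = dict(records)
    assert sorted(msa.ids) == sorted(originals)
    for idx, rid in enumerate(msa.ids):
        assert msa.ungapped(idx) == originals[rid]


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        msa = Msa(["a", "b"], ["MKVL", "MKVL"])
        assert compute_distances(msa, "poisson").matrix[0, 1] == 0.0

    def test_poisson_closed_form_at_p_0p1(self):
        msa = Msa(["a", "b"], ["A" * 10, "A" * 9 + "C"])
        d = compute_distances(msa, "poisson").matrix[0, 1]
        assert d == pytest.approx(0.10536, abs=1e-5)

    def test_p_distance_simple_count(self):
        msa = Msa(["a", "b"], ["AAAA", "AAAT"])
        assert compute_distances(msa, "p_distance").matrix[0, 1] == 0.25

    def test_pairwise_deletion_ignores_gapped_columns(self):
        msa = Msa(["a", "b"], ["A-AA", "AC-A"])
        assert compute_distances(msa, "p_distance").matrix[0, 1] == 0.0

    def test_no_comparable_positions_is_error(self):
        msa = Msa(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError, match="comparable"):
            compute_distances(msa, "p_distance")

    def test_saturated_pair_under_poisson_is_error(self):
        msa = Msa(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="Poisson"):
            compute_distances(msa, "poisson")


def random_additive_tree(rng, n_leaves):
    """Random binary unrooted tree; returns (leaf ids, distance matrix)."""
    nodes = {i: TreeNode(name=f"t{i}") for i in range(n_leaves)}
    dist = {(i, i): 0.0 for i in nodes}
    # track leaf-to-leaf distances through agglomeration
    leaf_dist = np.zeros((n_leaves, n_leaves))
    members = {i: [i] for i in range(n_leaves)}
    depth = {i: {i: 0.0} for i in range(n_leaves)}  # cluster -> leaf -> dist to join point
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        ci, cj = active[i], active[j]
        li, lj = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for a in members[ci]:
            for b in members[cj]:
                leaf_dist[a, b] = leaf_dist[b, a] = depth[ci][a] + li + depth[cj][b] + lj
        depth[nxt] = {a: depth[ci][a] + li for a in members[ci]}
        depth[nxt].update({b: depth[cj][b] + lj for b in members[cj]})
        members[nxt] = members[ci] + members[cj]
        active = [c for c in active if c not in (ci, cj)] + [nxt]
        nxt += 1
    ids = [f"t{i}" for i in range(n_leaves)]
    return ids, leaf_dist


def tree_leaf_distances(tree: PhyloTree):
    """Path-length metric induced by a tree."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            dists[node.name] = acc
            return
        for child, length in node.children:
            walk(child, acc + length)

    # distances via each edge: use recursive pairing through the root
    leaves = tree.leaf_ids
    out = {}

    def collect(node):
        if node.is_leaf:
            return {node.name: 0.0}
        merged = {}
        for child, length in node.children:
            below = collect(child)
            below = {k: v + length for k, v in below.items()}
            for other_name, other_d in merged.items():
                for name, d in below.items():
                    out[frozenset((other_name, name))] = other_d + d
            merged.update(below)
        return merged

    collect(tree.root)
    n = len(leaves)
    mat = np.zeros((n, n))
    for (a, b), d in ((tuple(k), v) for k, v in out.items()):
        ia, ib = leaves.index(a), leaves.index(b)
        mat[ia, ib] = mat[ib, ia] = d
    return leaves, mat


class TestNeighborJoining:
    def test_three_taxa_solve_three_point_formulas(self):
        ids = ["a", "b", "c"]
        mat = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(ids, mat, "p_distance"))
        lengths = {child.name: length for child, length in tree.root.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_eight_taxon_matrices_recovered_exactly(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            ids, mat = random_additive_tree(rng, 8)
            tree = nj_tree(DistanceMatrix(ids, mat, "p_distance"))
            leaves, realized = tree_leaf_distances(tree)
            order = [leaves.index(i) for i in ids]
            assert np.allclose(realized[np.ix_(order, order)], mat, atol=1e-9)

    def test_four_taxon_split_recovered(self):
        ids = ["A", "B", "C", "D"]
        mat = np.array(
            [
                [0.0, 0.2, 1.0, 1.1],
                [0.2, 0.0, 1.1, 1.0],
                [1.0, 1.1, 0.0, 0.3],
                [1.1, 1.0, 0.3, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(ids, mat, "p_distance"))
        splits = {frozenset(s) for s in tree.splits()}
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits

    def test_non_symmetric_input_rejected(self):
        mat = np.array([[0.0, 1.0, 2.0], [0.9, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b", "c"], mat, "p_distance")

    def test_agrees_with_dendropy_on_additive_matrix(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(11)
        ids, mat = random_additive_tree(rng, 7)
        mine = nj_tree(DistanceMatrix(ids, mat, "p_distance"))
        csv = "," + ",".join(ids) + "\n"
        for i, rid in enumerate(ids):
            csv += rid + "," + ",".join(str(x) for x in mat[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        ref = min(ids)
        their_splits = set()
        for edge in dtree.preorder_edge_iter():
            leaves = {
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            }
            if 2 <= len(leaves) <= len(ids) - 2:
                side = frozenset(leaves if ref not in leaves else set(ids) - leaves)
                their_splits.add(side)
        assert set(mine.splits()) == their_splits


class TestBootstrap:
    def _separated_msa(self):
        return Msa(
            ["a", "b", "c", "d"],
            ["AAAAAAAAAC", "AAAAAAAAAG", "TTTTTTTTTC", "TTTTTTTTTG"],
        )

    def test_clean_split_gets_full_support(self):
        tree = bootstrap_support(self._separated_msa(), 200, seed=1, model="p_distance")
        supports = [n.support for n in tree.splits().values()]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        tree = bootstrap_support(self._separated_msa(), 1, seed=2, model="p_distance")
        assert all(n.support in (0.0, 100.0) for n in tree.splits().values())

    def test_fixed_seed_reproducible(self):
        t1 = bootstrap_support(self._separated_msa(), 50, seed=3, model="p_distance")
        t2 = bootstrap_support(self._separated_msa(), 50, seed=3, model="p_distance")
        assert t1.to_newick() == t2.to_newick()

    def test_supports_invariant_to_leaf_input_order(self):
        msa = self._separated_msa()
        shuffled = Msa(
            [msa.ids[2], msa.ids[0], msa.ids[3], msa.ids[1]],
            [msa.rows[2], msa.rows[0], msa.rows[3], msa.rows[1]],
        )
        t1 = bootstrap_support(msa, 100, seed=4, model="p_distance")
        t2 = bootstrap_support(shuffled, 100, seed=4, model="p_distance")
        s1 = {split: n.support for split, n in t1.splits().items()}
        s2 = {split: n.support for split, n in t2.splits().items()}
        assert s1 == s2

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._separated_msa(), 0, seed=1)


class TestClanAssignment:
    def _references(self, rng):
        refs = [
            (f"REF_{clan}", "".join(AA[k] for k in rng.integers(0, 20, 120)))
            for clan in ("A1", "B2", "B3")
        ]
        return SequenceSet(refs, PROTEIN), {r: r.removeprefix("REF_") for r, _ in refs}

    def test_identical_query_gets_reference_clan_with_margin(self):
        rng = np.random.default_rng(20)
        refs, clans = self._references(rng)
        queries = SequenceSet([("q1", refs["REF_A1"])], PROTEIN)
        (call,) = assign_clans(queries, refs, clans)
        assert call.clan == "A1"
        assert call.margin > 0

    def test_five_percent_mutated_query_maps_to_source_clan(self):
        rng = np.random.default_rng(21)
        refs, clans = self._references(rng)
        base = list(refs["REF_B2"])
        for pos in rng.choice(len(base), size=6, replace=False):
            base[pos] = AA[rng.integers(0, 20)]
        queries = SequenceSet([("q1", "".join(base))], PROTEIN)
        (call,) = assign_clans(queries, refs, clans)
        assert call.clan == "B2"

    def test_equidistant_query_takes_lower_sorted_clan_with_zero_margin(self):
        seq = "MKVLLATGHE" * 10
        refs = SequenceSet([("r1", seq), ("r2", seq)], PROTEIN)
        clans = {"r1": "B4", "r2": "A2"}
        queries = SequenceSet([("q1", seq)], PROTEIN)
        (call,) = assign_clans(queries, refs, clans)
        assert call.clan == "A2"
        assert call.margin == 0.0

    def test_subfamily_override_wins(self):
        rng = np.random.default_rng(22)
        refs, clans = self._references(rng)
        queries = SequenceSet([("q1", refs["REF_A1"])], PROTEIN)
        (call,) = assign_clans(queries, refs, clans, {"q1": "RAV"})
        assert call.clan == "RAV"

    def test_empty_reference_set_rejected(self):
        queries = SequenceSet([("q1", "MKV")], PROTEIN)
        with pytest.raises(ValueError, match="empty"):
            assign_clans(queries, SequenceSet([], PROTEIN), {})
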