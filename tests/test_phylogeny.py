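import itertools

import numpy as np
import pytest

from caseikit.pairwise import PairwiseMatrix
from caseikit.phylogeny import (
    PhyloTree,
    Supermatrix,
    bootstrap_support,
    concatenate,
    extract_clades,
    nj_tree,
    p_distance,
    progressive_msa,
)


def tree_bipartitions(ptree: PhyloTree):
    return set(ptree.bipartitions())


class TestProgressiveMsa:
    def test_identical_sequences_gap_free(self):
        seqs = {f"t{i}": "ATGAAACCCGGG" for i in range(4)}
        aln = progressive_msa(seqs)
        assert all(s == "ATGAAACCCGGG" for s in aln.values())

    def test_single_sequence_unchanged(self):
        assert progressive_msa({"t": "ACGT"}) == {"t": "ACGT"}

    def test_single_insertion_pair(self):
        # one gap column, four identities, as the pairwise DP oracle demands
        aln = progressive_msa({"a": "ACGT", "b": "ACGGT"})
        assert len(aln["a"]) == 5
        assert aln["a"].count("-") == 1
        matches = sum(1 for x, y in zip(aln["a"], aln["b"]) if x == y and x != "-")
        assert matches == 4

    def test_deterministic(self):
        rng = np.random.default_rng(97)
        seqs = {
            f"t{i}": "".join(rng.choice(np.array(list("ACGT")), size=60))
            for i in range(5)
        }
        assert progressive_msa(seqs) == progressive_msa(seqs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa({})


class TestSupermatrix:
    def test_concatenate_partitions(self):
        alignments = {
            "m1": {"a": "A" * 10, "b": "C" * 10},
            "m2": {"a": "G" * 20, "b": "T" * 20},
        }
        sm = concatenate(alignments, ["a", "b"])
        assert sm.width == 30
        assert sm.partitions == {"m1": (1, 10), "m2": (11, 30)}

    def test_missing_taxon_gets_gap_block(self):
        alignments = {"m1": {"a": "ACGT", "b": "ACGT"}, "m2": {"a": "GGGG"}}
        sm = concatenate(alignments, ["a", "b"])
        assert sm.rows["b"][4:] == "----"

    def test_round_trip_by_partition_map(self):
        alignments = {
            "m1": {"a": "ACGT", "b": "AGGT"},
            "m2": {"a": "TTTT", "b": "TTAT"},
        }
        sm = concatenate(alignments, ["a", "b"])
        for marker, block in alignments.items():
            assert sm.marker_block(marker) == block

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError):
            concatenate({}, ["a"])


class TestPDistance:
    def test_identical_rows_zero(self):
        sm = concatenate({"m": {"a": "ACGT" * 10, "b": "ACGT" * 10}}, ["a", "b"])
        assert p_distance(sm).values[0, 1] == 0.0

    def test_five_of_hundred_differences(self):
        row_a = "A" * 100
        row_b = "C" * 5 + "A" * 95
        sm = concatenate({"m": {"a": row_a, "b": row_b}}, ["a", "b"])
        assert p_distance(sm).values[0, 1] == pytest.approx(0.05)

    def test_gapped_columns_excluded(self):
        sm = concatenate({"m": {"a": "AC-T", "b": "ACGT"}}, ["a", "b"])
        assert p_distance(sm).values[0, 1] == 0.0  # 3 comparable, 0 differ

    def test_jukes_cantor_of_zero_is_zero(self):
        sm = concatenate({"m": {"a": "ACGT", "b": "ACGT"}}, ["a", "b"])
        assert p_distance(sm, jukes_cantor=True).values[0, 1] == 0.0


def additive_matrix_from_tree(branch):
    """5-taxon tree ((a,b),(c,d),e) with named branch lengths -> distances."""
    taxa = list("abcde")
    paths = {
        ("a", "b"): branch["a"] + branch["b"],
        ("a", "c"): branch["a"] + branch["ab"] + branch["cd"] + branch["c"],
        ("a", "d"): branch["a"] + branch["ab"] + branch["cd"] + branch["d"],
        ("a", "e"): branch["a"] + branch["ab"] + branch["e"],
        ("b", "c"): branch["b"] + branch["ab"] + branch["cd"] + branch["c"],
        ("b", "d"): branch["b"] + branch["ab"] + branch["cd"] + branch["d"],
        ("b", "e"): branch["b"] + branch["ab"] + branch["e"],
        ("c", "d"): branch["c"] + branch["d"],
        ("c", "e"): branch["c"] + branch["cd"] + branch["e"],
        ("d", "e"): branch["d"] + branch["cd"] + branch["e"],
    }
    vals = np.zeros((5, 5))
    for (x, y), d in paths.items():
        i, j = taxa.index(x), taxa.index(y)
        vals[i, j] = vals[j, i] = d
    return PairwiseMatrix(taxa, vals, "PDIST")


class TestNjTree:
    def test_three_taxon_closed_form(self):
        # d(a,b)=0.3, d(a,c)=0.5, d(b,c)=0.6 -> a=0.1, b=0.2, c=0.4
        vals = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = nj_tree(PairwiseMatrix(["a", "b", "c"], vals, "PDIST"))
        lengths = {t.name: t.length for t in tree.tree.tips()}
        assert lengths["a"] == pytest.approx(0.1, abs=1e-9)
        assert lengths["b"] == pytest.approx(0.2, abs=1e-9)
        assert lengths["c"] == pytest.approx(0.4, abs=1e-9)

    def test_additive_five_taxon_topology_recovered(self):
        # oracle: of the 15 unrooted topologies only the generating one is
        # additive; NJ must recover its single internal split set
        rng = np.random.default_rng(101)
        for _ in range(5):
            branch = {k: float(rng.uniform(0.05, 0.4)) for k in
                      ("a", "b", "c", "d", "e", "ab", "cd")}
            D = additive_matrix_from_tree(branch)
            tree = nj_tree(D)
            bips = {frozenset(b) for b in tree.bipartitions()}
            expected_sides = [{"a", "b"}, {"c", "d"}]
            all_taxa = set("abcde")
            for side in expected_sides:
                assert (
                    frozenset(side) in bips or frozenset(all_taxa - side) in bips
                )

    def test_additive_matrix_reproduced_along_tree_paths(self):
        rng = np.random.default_rng(103)
        branch = {k: float(rng.uniform(0.05, 0.4)) for k in
                  ("a", "b", "c", "d", "e", "ab", "cd")}
        D = additive_matrix_from_tree(branch)
        tree = nj_tree(D).tree
        for x, y in itertools.combinations("abcde", 2):
            tx = next(t for t in tree.tips() if t.name == x)
            d = tx.distance(next(t for t in tree.tips() if t.name == y))
            i, j = D.genome_ids.index(x), D.genome_ids.index(y)
            assert d == pytest.approx(D.values[i, j], abs=1e-9)

    def test_missing_distances_rejected(self):
        vals = np.array([[0.0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="missing"):
            nj_tree(PairwiseMatrix(["a", "b", "c"], vals, "PDIST"))


class TestBootstrap:
    def _sm(self, seed=107, n_taxa=6, width=300):
        rng = np.random.default_rng(seed)
        base = rng.choice(np.array(list("ACGT")), size=width)
        rows = {}
        for i in range(n_taxa):
            row = base.copy()
            n_mut = 5 + 10 * (i // 2)  # three pairs at increasing depth
            pos = rng.choice(width, size=n_mut, replace=False)
            for p in pos:
                row[p] = rng.choice([b for b in "ACGT" if b != row[p]])
            rows[f"t{i}"] = "".join(row)
        return Supermatrix(list(rows), rows, {"m": (1, width)})

    def test_zero_reps_tree_without_supports(self):
        tree = bootstrap_support(self._sm(), n_reps=0)
        assert all(s is None for _, s in tree.bipartitions().values())

    def test_degenerate_all_identical_rows(self):
        rows = {f"t{i}": "ACGT" * 50 for i in range(4)}
        sm = Supermatrix(list(rows), rows, {"m": (1, 200)})
        tree = bootstrap_support(sm, n_reps=10, seed=1)
        assert all(s is None for _, s in tree.bipartitions().values())

    def test_supports_reproducible_and_bounded(self):
        sm = self._sm()
        t1 = bootstrap_support(sm, n_reps=50, seed=3)
        t2 = bootstrap_support(sm, n_reps=50, seed=3)
        b1, b2 = t1.bipartitions(), t2.bipartitions()
        assert {k: v[1] for k, v in b1.items()} == {k: v[1] for k, v in b2.items()}
        assert all(0 <= s <= 100 for _, s in b1.values() if s is not None)

    def test_supports_invariant_to_taxon_relabeling(self):
        sm = self._sm()
        relabel = {t: f"x{t}" for t in sm.taxa}
        sm2 = Supermatrix(
            [relabel[t] for t in sm.taxa],
            {relabel[t]: sm.rows[t] for t in sm.taxa},
            dict(sm.partitions),
        )
        s1 = sorted(
            v[1] for v in bootstrap_support(sm, 50, seed=5).bipartitions().values()
        )
        s2 = sorted(
            v[1] for v in bootstrap_support(sm2, 50, seed=5).bipartitions().values()
        )
        assert s1 == s2


class TestExtractClades:
    def test_single_shallow_clade(self):
        # no deep structure: everything lands in one clade
        rng = np.random.default_rng(109)
        base = rng.choice(np.array(list("ACGT")), size=400)
        rows = {}
        for i in range(5):
            row = base.copy()
            for p in rng.choice(400, size=4, replace=False):
                row[p] = rng.choice([b for b in "ACGT" if b != row[p]])
            rows[f"t{i}"] = "".join(row)
        out = base.copy()
        for p in rng.choice(400, size=120, replace=False):
            out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
        rows["og"] = "".join(out)
        sm = Supermatrix(list(rows), rows, {"m": (1, 400)})
        tree = bootstrap_support(sm, n_reps=20, seed=7)
        ca = extract_clades(tree, "og")
        assert len(set(ca.clades.values())) == 1

    def test_missing_outgroup_rejected(self, small_dataset):
        rows = {"a": "ACGT", "b": "ACGT", "c": "AGGT"}
        sm = Supermatrix(list(rows), rows, {"m": (1, 4)})
        tree = bootstrap_support(sm, n_reps=0)
        with pytest.raises(ValueError, match="outgroup"):
            extract_clades(tree, "nope")

    def test_weakly_supported_edges_not_cut(self):
        # an edge with support below the floor cannot define a clade boundary
        rng = np.random.default_rng(113)
        base = rng.choice(np.array(list("ACGT")), size=300)

        def variant(n):
            row = base.copy()
            for p in rng.choice(300, size=n, replace=False):
                row[p] = rng.choice([b for b in "ACGT" if b != row[p]])
            return "".join(row)

        rows = {f"t{i}": variant(3) for i in range(6)}
        rows["og"] = variant(100)
        sm = Supermatrix(list(rows), rows, {"m": (1, 300)})
        tree = bootstrap_support(sm, n_reps=30, seed=11)
        # all internal structure among t* is noise: supports are low, no cuts
        ca = extract_clades(tree, "og", min_support=70)
        assert len(set(ca.clades.values())) == 1
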