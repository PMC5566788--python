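import itertools

import numpy as np
import pytest

from caseikit.orthology import (
    OrthogroupTable,
    all_vs_all,
    core_accessory,
    infer_orthogroups,
    outgroup_augment,
    single_copy_markers,
    MarkerSet,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, length):
    return "M" + "".join(rng.choice(np.array(list(AAS)), size=length - 1))


def mutate_protein(rng, seq, rate):
    out = list(seq)
    n = round(rate * len(seq))
    for p in rng.choice(np.arange(1, len(seq)), size=n, replace=False):
        out[p] = rng.choice([a for a in AAS if a != seq[p]])
    return "".join(out)


@pytest.fixture(scope="module")
def toy_proteomes():
    rng = np.random.default_rng(53)
    base = [random_protein(rng, 150) for _ in range(6)]
    proteomes = {}
    for g in ("g1", "g2", "g3"):
        proteomes[g] = {
            f"{g}_p{i}": mutate_protein(rng, p, 0.10) for i, p in enumerate(base)
        }
    return proteomes


class TestAllVsAll:
    def test_identical_proteomes_full_identity_edges(self):
        rng = np.random.default_rng(59)
        prots = {f"p{i}": random_protein(rng, 120) for i in range(5)}
        proteomes = {"g1": prots, "g2": {f"x{i}": s for i, (k, s) in enumerate(prots.items())}}
        edges = all_vs_all(proteomes)
        cross = [e for e in edges if e.protein_a[0] != e.protein_b[0]]
        assert len(cross) == 5
        assert all(e.identity == 100.0 for e in cross)
        assert all(e.normalized_score == pytest.approx(1.0) for e in cross)

    def test_planted_divergence_thresholds(self):
        rng = np.random.default_rng(61)
        base = random_protein(rng, 200)
        proteomes = {
            "g1": {"orig": base},
            "g2": {"near": mutate_protein(rng, base, 0.30), "far": mutate_protein(rng, base, 0.60)},
        }
        edges = all_vs_all(proteomes)
        partners = {e.protein_b[1] for e in edges} | {e.protein_a[1] for e in edges}
        assert "near" in partners  # ~70% identity passes the 50% floor
        far_edges = [e for e in edges if "far" in (e.protein_a[1], e.protein_b[1])]
        assert far_edges == []  # ~40% identity stays below the floor

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty proteome"):
            all_vs_all({"g1": {"p": "MKLV"}, "g2": {}})


class TestInferOrthogroups:
    def test_no_edges_yield_singletons(self):
        rng = np.random.default_rng(67)
        proteomes = {
            "g1": {"a": random_protein(rng, 100)},
            "g2": {"b": random_protein(rng, 100)},
        }
        table = infer_orthogroups([], proteomes)
        assert table.n_orthogroups == 2
        assert all(table.presence(og) == 1 for og in table.members)

    def test_three_identical_proteomes(self, toy_proteomes):
        edges = all_vs_all(toy_proteomes)
        table = infer_orthogroups(edges, toy_proteomes)
        sizes = sorted(
            sum(len(v) for v in per.values()) for per in table.members.values()
        )
        assert sizes == [3] * 6

    def test_partition_property(self, toy_proteomes):
        edges = all_vs_all(toy_proteomes)
        table = infer_orthogroups(edges, toy_proteomes)
        total_genes = sum(len(p) for p in toy_proteomes.values())
        assert sum(
            len(v) for per in table.members.values() for v in per.values()
        ) == total_genes

    def test_matches_bruteforce_connected_components(self):
        # random edge sets over <= 50 proteins against a naive component oracle
        rng = np.random.default_rng(71)
        for _ in range(10):
            n = int(rng.integers(5, 50))
            proteomes = {"g": {f"p{i}": "MKLVA" for i in range(n)}}
            keys = [("g", f"p{i}") for i in range(n)]
            from caseikit.orthology import SimilarityEdge

            edges = []
            adj = {k: set() for k in keys}
            for _ in range(int(rng.integers(0, 2 * n))):
                i, j = rng.integers(n, size=2)
                if i == j:
                    continue
                score = float(rng.random())
                edges.append(
                    SimilarityEdge(keys[i], keys[j], 100.0, 1.0, score)
                )
                if score >= 0.5:
                    adj[keys[i]].add(keys[j])
                    adj[keys[j]].add(keys[i])
            # oracle: BFS components over the pruned graph
            seen, comps = set(), []
            for k in keys:
                if k in seen:
                    continue
                stack, comp = [k], set()
                while stack:
                    cur = stack.pop()
                    if cur in comp:
                        continue
                    comp.add(cur)
                    stack.extend(adj[cur] - comp)
                seen |= comp
                comps.append(frozenset(comp))
            table = infer_orthogroups(edges, proteomes)
            got = {
                frozenset(("g", gene) for genes in per.values() for gene in genes)
                for per in table.members.values()
            }
            assert got == set(comps)

    def test_planted_duplication_counted(self):
        rng = np.random.default_rng(73)
        base = random_protein(rng, 150)
        proteomes = {
            "g1": {"a": base, "a2": mutate_protein(rng, base, 0.05)},
            "g2": {"b": mutate_protein(rng, base, 0.05)},
        }
        table = infer_orthogroups(all_vs_all(proteomes), proteomes)
        counts = table.counts()
        og = [o for o in table.members if table.presence(o) == 2]
        assert len(og) == 1
        assert counts.loc["g1", og[0]] == 2


class TestCoreAccessory:
    def _table(self, presence_counts, n_genomes):
        members = {}
        for i, k in enumerate(presence_counts):
            og = f"OG{i:04d}"
            members[og] = {f"g{j}": [f"gene{i}_{j}"] for j in range(k)}
        return OrthogroupTable(members, [f"g{j}" for j in range(n_genomes)])

    def test_strict_95_percent_boundary(self):
        table = self._table([96, 95, 100], 100)
        summary = core_accessory(table, core_frac=0.95)
        # 96/100 core, 95/100 accessory (strict inequality), 100/100 core
        assert summary.n_core == 2
        assert summary.n_accessory == 1
        assert summary.n_core + summary.n_accessory == table.n_orthogroups

    def test_recovers_generator_core_count(self, small_dataset):
        proteomes = small_dataset.proteomes()
        edges = all_vs_all(proteomes)
        table = infer_orthogroups(edges, proteomes)
        summary = core_accessory(table)
        assert summary.n_core == len(small_dataset.truth.core_orthogroups)


class TestMarkers:
    def test_duplicated_orthogroup_excluded(self, toy_proteomes):
        proteomes = {g: dict(p) for g, p in toy_proteomes.items()}
        dup_src = next(iter(proteomes["g1"].values()))
        proteomes["g1"]["dup"] = dup_src  # now one family has 2 copies in g1
        edges = all_vs_all(proteomes)
        table = infer_orthogroups(edges, proteomes)
        markers = single_copy_markers(table, proteomes, edges, min_presence=0.9)
        for og in markers.orthogroup_ids:
            assert all(len(v) <= 1 for v in table.members[og].values())
        assert len(markers.orthogroup_ids) == 5  # the duplicated family dropped

    def test_monotone_in_min_presence(self, small_dataset):
        proteomes = small_dataset.proteomes()
        edges = all_vs_all(proteomes)
        table = infer_orthogroups(edges, proteomes)
        sets = []
        for presence in (0.5, 0.8, 0.96):
            m = single_copy_markers(table, proteomes, edges, min_presence=presence)
            sets.append(set(m.orthogroup_ids))
        assert sets[2] <= sets[1] <= sets[0]

    def test_empty_result_warns(self):
        table = OrthogroupTable({"OG0": {"g1": ["a"]}}, ["g1", "g2", "g3"])
        proteomes = {"g1": {"a": "MKLV"}, "g2": {"b": "MWWW"}, "g3": {"c": "MCCC"}}
        with pytest.warns(UserWarning):
            markers = single_copy_markers(table, proteomes, [])
        assert markers.orthogroup_ids == []


class TestOutgroupAugment:
    def _markers(self, rep):
        return MarkerSet(["og1"], {"og1": {"g1": "p1"}}, {"og1": 1.0}, {"og1": 100.0})

    def test_identical_outgroup_always_augments(self):
        rng = np.random.default_rng(79)
        rep = random_protein(rng, 200)
        aug = outgroup_augment(self._markers(rep), {"og1": rep}, {"o1": rep})
        assert aug["og1"] == "o1"

    def test_low_identity_hit_rejected(self):
        rng = np.random.default_rng(83)
        rep = random_protein(rng, 200)
        weak = mutate_protein(rng, rep, 0.55)  # ~45% identity < 50% floor
        aug = outgroup_augment(self._markers(rep), {"og1": rep}, {"o1": weak})
        assert aug["og1"] is None

    def test_low_coverage_hit_rejected(self):
        rng = np.random.default_rng(89)
        rep = random_protein(rng, 200)
        fragment = rep[:140]  # 70% of the marker < 75% coverage floor
        aug = outgroup_augment(self._markers(rep), {"og1": rep}, {"o1": fragment})
        assert aug["og1"] is None

    def test_empty_outgroup_rejected(self):
        with pytest.raises(ValueError):
            outgroup_augment(self._markers("MKLV"), {"og1": "MKLV"}, {})
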