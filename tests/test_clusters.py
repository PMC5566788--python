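import itertools

import numpy as np
import pytest

from caseikit.clusters import (
    FrameshiftCall,
    detect_frameshift,
    find_gt_clusters,
    find_srr,
    order_contigs,
    reconstruct_consensus,
    scan_motifs,
    serine_fraction,
    cluster_presence,
)
from caseikit.genome_io import GenomeRecord, GeneCall, reverse_complement
from caseikit.screen import FeatureCall

from conftest import random_genome


def gt_call(gene_id, family="GT4"):
    return FeatureCall(genome_id="g", gene_id=gene_id, family=family, route="reference")


def gene_at(gene_id, start, end, translation="M" + "A" * 50):
    return GeneCall(
        gene_id=gene_id, contig_id="c1", start=start, end=end, strand="+",
        length=end - start + 1 if (end - start + 1) % 3 == 0 else ((end - start + 1) // 3) * 3,
        translation=translation,
    )


def make_gene(gene_id, start, length):
    # length forced to a codon multiple
    length = (length // 3) * 3
    return GeneCall(
        gene_id=gene_id, contig_id="c1", start=start, end=start + length - 1,
        strand="+", length=length, translation="M" + "A" * (length // 3 - 2),
    )


class TestGtClusterRule:
    def _genes(self, spans):
        return [make_gene(f"g{i}", s, e - s + 1) for i, (s, e) in enumerate(spans)]

    def test_gaps_at_and_below_5kb_form_cluster(self):
        genes = self._genes([(1, 900), (4901, 5800), (10801, 11700)])
        feats = [gt_call(g.gene_id) for g in genes]
        # gaps: 4901-900-1 = 4000 and 10801-5800-1 = 5000
        clusters = find_gt_clusters(genes, feats)
        assert len(clusters) == 1
        assert clusters[0].gaps == [4000, 5000]

    def test_gap_of_5001_breaks_cluster(self):
        genes = self._genes([(1, 900), (4901, 5800), (10802, 11701)])
        feats = [gt_call(g.gene_id) for g in genes]
        assert find_gt_clusters(genes, feats) == []

    def test_two_gts_insufficient(self):
        genes = self._genes([(1, 900), (2001, 2900)])
        feats = [gt_call(g.gene_id) for g in genes]
        assert find_gt_clusters(genes, feats) == []

    def test_non_gt_genes_inside_span_are_members(self):
        genes = self._genes([(1, 900), (1001, 1900), (2001, 2900), (3001, 3900)])
        feats = [gt_call(g.gene_id) for g in genes if g.gene_id != "g1"]
        (cluster,) = find_gt_clusters(genes, feats)
        assert cluster.gt_gene_ids == ["g0", "g2", "g3"]
        assert "g1" in cluster.member_gene_ids

    def test_matches_bruteforce_window_scan(self):
        # all arrangements of <= 6 GT genes on a 30-kb grid vs a naive scan
        rng = np.random.default_rng(179)
        for _ in range(30):
            n = int(rng.integers(1, 7))
            starts = np.sort(rng.choice(np.arange(1, 30_000, 600), size=n, replace=False))
            genes = [make_gene(f"g{i}", int(s), 300) for i, s in enumerate(starts)]
            feats = [gt_call(g.gene_id) for g in genes]
            clusters = find_gt_clusters(genes, feats, min_gts=3, max_gap=2_000)
            # oracle: maximal runs by direct successive-gap scan
            runs, run = [], [genes[0]] if genes else []
            for prev, nxt in zip(genes, genes[1:]):
                if nxt.start - prev.end - 1 > 2_000:
                    runs.append(run)
                    run = [nxt]
                else:
                    run.append(nxt)
            runs.append(run)
            expected = [tuple(g.gene_id for g in r) for r in runs if len(r) >= 3]
            got = [tuple(c.gt_gene_ids) for c in clusters]
            assert got == expected


class TestClusterPresence:
    def test_planted_clade_specific_cluster(self):
        genomes = [f"b{i}" for i in range(10)] + ["a0", "c0"]
        clades = {g: g[0].upper() for g in genomes}
        ogs = [f"og{i}" for i in range(4)]
        clusters_by_genome = {g: [] for g in genomes}
        og_presence = {og: set() for og in ogs}
        gene_og = {}
        for g in genomes[:6]:  # cluster present in 6 of 10 clade-B genomes
            genes = [make_gene(f"{g}_x{i}", 1 + 1000 * i, 900) for i in range(4)]
            from caseikit.clusters import GtCluster

            clusters_by_genome[g] = [
                GtCluster(g, "c1", [x.gene_id for x in genes[:3]], ["GT4"] * 3,
                          [x.gene_id for x in genes], 1, 4000, [100, 100])
            ]
            for i, x in enumerate(genes):
                gene_og[(g, x.gene_id)] = ogs[i]
                og_presence[ogs[i]].add(g)
        presence, specificity, members = cluster_presence(
            clusters_by_genome, gene_og, clades, og_presence
        )
        (label,) = presence.index
        assert presence.loc[label].sum() == 6
        assert specificity[label] == "B"

    def test_jaccard_below_half_keeps_archetypes_distinct(self):
        from caseikit.clusters import GtCluster

        g1 = GtCluster("g1", "c1", ["a"], ["GT4"], ["a"], 1, 900, [])
        g2 = GtCluster("g2", "c1", ["b"], ["GT4"], ["b"], 1, 900, [])
        gene_og = {("g1", "a"): "og1", ("g2", "b"): "og2"}
        presence, _, members = cluster_presence(
            {"g1": [g1], "g2": [g2]}, gene_og, {"g1": "A", "g2": "A"},
            {"og1": {"g1"}, "og2": {"g2"}},
        )
        assert len(presence) == 2


class TestSerineAndMotifs:
    def test_serine_fraction_extremes(self):
        assert serine_fraction("SSSS") == 1.0
        assert serine_fraction("ACDE") == 0.0
        with pytest.raises(ValueError):
            serine_fraction("")

    def test_serine_fraction_permutation_invariant(self):
        rng = np.random.default_rng(181)
        prot = "".join(rng.choice(np.array(list("SACDEFG")), size=200))
        shuffled = "".join(rng.permutation(list(prot)))
        assert serine_fraction(prot) == serine_fraction(shuffled)

    def test_n_motif_position(self):
        prot = "MA" + "KAYKAGKAW" + "G" * 200
        n_pos, _ = scan_motifs(prot)
        assert n_pos == 3

    def test_lpqts_anchor_variant_detected(self):
        prot = "M" + "A" * 200 + "LPQTS" + "GG"
        _, anchor = scan_motifs(prot)
        assert anchor == "LPQTS"
        _, strict = scan_motifs(prot, strict_anchor=True)
        assert strict is None

    def test_motif_free_protein(self):
        assert scan_motifs("M" + "G" * 300) == (None, None)

    def test_motif_outside_window_not_reported(self):
        prot = "M" + "A" * 200 + "KAYKAGKAW" + "A" * 200
        n_pos, _ = scan_motifs(prot, n_window=120)
        assert n_pos is None


class TestFindSrr:
    def _srr_gene(self, gene_id, n_aa, ser_frac, with_n=True, with_c=True):
        rng = np.random.default_rng(hash(gene_id) % 2**31)
        n_ser = round(ser_frac * n_aa)
        body = ["A"] * (n_aa - n_ser) + ["S"] * n_ser
        rng.shuffle(body)
        prot = list("M" + "".join(body[1:]))
        if with_n:
            prot[9:18] = list("KAYKAGKAW")
        if with_c:
            prot[-8:-3] = list("LPKTG")
        prot = "".join(prot)
        return GeneCall(
            gene_id=gene_id, contig_id="c1", start=1, end=3 * (n_aa + 1),
            strand="+", length=3 * (n_aa + 1), translation=prot,
        )

    def test_intact_adhesin_called(self):
        calls = find_srr([self._srr_gene("srr", 7370, 0.38)])
        assert len(calls) == 1
        assert calls[0].intact
        assert calls[0].serine_fraction == pytest.approx(0.38, abs=0.01)

    def test_defective_copy_flagged(self):
        calls = find_srr([self._srr_gene("srr", 2950, 0.15, with_n=False)])
        assert not calls[0].intact
        assert calls[0].defect == "truncation"

    def test_short_or_serine_poor_not_called(self):
        short = self._srr_gene("short", 700, 0.38)
        poor = self._srr_gene("poor", 3000, 0.02)
        assert find_srr([short, poor]) == []

    def test_sorted_by_length_descending(self):
        calls = find_srr([self._srr_gene("a", 2950, 0.15), self._srr_gene("b", 7370, 0.38)])
        assert [c.gene_id for c in calls] == ["b", "a"]


class TestDetectFrameshift:
    def test_a5_to_a6_insertion(self):
        rng = np.random.default_rng(191)
        intact = random_genome(rng, 3000)
        pos = 840
        intact = intact[:pos] + "AAAAA" + intact[pos + 5 :]
        mutated = intact[:pos] + "A" + intact[pos:]
        call = detect_frameshift(mutated, intact)
        assert call.type == "insertion"
        assert call.length == 1
        assert call.homopolymer_base == "A"
        assert call.homopolymer_run == 5
        assert abs(call.position - pos) <= 5  # placement within the A-run
        assert call.effect == "internal_split"

    def test_dinucleotide_deletion_near_start(self):
        rng = np.random.default_rng(193)
        intact = random_genome(rng, 3000)
        mutated = intact[:100] + intact[102:]
        call = detect_frameshift(mutated, intact)
        assert call.type == "deletion"
        assert call.length == 2
        assert call.effect == "n_truncation"
        assert abs(call.position - 101) <= 3

    def test_in_frame_indel_not_reported(self):
        rng = np.random.default_rng(197)
        intact = random_genome(rng, 3000)
        mutated = intact[:900] + intact[903:]
        assert detect_frameshift(mutated, intact) is None

    def test_incomparable_sequences_rejected(self):
        rng = np.random.default_rng(199)
        with pytest.raises(ValueError, match="not comparable"):
            detect_frameshift(random_genome(rng, 1000), random_genome(rng, 1000))

    def test_generator_planted_frameshifts_recovered(self, small_dataset):
        from caseikit.simulate import plant_frameshift, FrameshiftPlan

        rng = np.random.default_rng(0)
        gid = small_dataset.truth.locus_genomes[0]
        srr_genes = {
            fam: small_dataset.gene_dna[gid][genes[0]]
            for fam, genes in small_dataset.truth.families[gid].items()
            if fam in ("srr1", "srr2")
        }
        mutated, truth = plant_frameshift(
            srr_genes["srr2"], FrameshiftPlan("srr2", "a_insertion", 0.038), rng
        )
        call = detect_frameshift(mutated, srr_genes["srr2"])
        assert (call.type, call.length) == ("insertion", 1)
        assert abs(call.position - truth.position) <= truth.homopolymer_run
        mutated, truth = plant_frameshift(
            srr_genes["srr1"], FrameshiftPlan("srr1", "deletion", 0.011), rng
        )
        call = detect_frameshift(mutated, srr_genes["srr1"])
        assert (call.type, call.length) == ("deletion", 2)


class TestConsensus:
    def test_exact_overlap_concatenation(self):
        rng = np.random.default_rng(211)
        full = random_genome(rng, 600)
        frags = {"f1": full[:350], "f2": full[250:]}
        assert reconstruct_consensus(frags) == full

    def test_majority_vote_on_disagreement(self):
        rng = np.random.default_rng(223)
        full = random_genome(rng, 600)
        variant = list(full)
        variant[300] = "A" if full[300] != "A" else "C"
        frags = {"f1": full[:400], "f2": full[100:500], "f3": "".join(variant)[200:]}
        cons = reconstruct_consensus(frags)
        assert cons == full  # 2-vs-1 majority keeps the original base

    def test_non_overlapping_fragments_rejected(self):
        rng = np.random.default_rng(227)
        full = random_genome(rng, 900)
        with pytest.raises(ValueError, match="overlap"):
            reconstruct_consensus({"f1": full[:200], "f2": full[700:]})

    def test_split_adhesin_reconstructed_with_both_motifs(self, small_dataset):
        from caseikit.clusters import scan_motifs
        from Bio.Seq import Seq

        gid = small_dataset.truth.locus_genomes[0]
        srr2 = small_dataset.gene_dna[gid][
            small_dataset.truth.families[gid]["srr2"][0]
        ]
        # partial copies as contig breaks would leave them, with overlaps
        frags = {"p1": srr2[:9_000], "p2": srr2[8_000:16_000], "p3": srr2[15_000:]}
        cons = reconstruct_consensus(frags)
        assert cons == srr2
        prot = str(Seq(cons[:-3]).translate(table=11))
        n_pos, anchor = scan_motifs(prot)
        assert n_pos is not None and anchor is not None


class TestOrderContigs:
    def test_shuffled_pieces_restored(self):
        rng = np.random.default_rng(229)
        ref_seq = random_genome(rng, 30_000)
        ref = GenomeRecord("ref", [("r1", ref_seq)])
        pieces = [ref_seq[:12_000], ref_seq[12_000:20_000], ref_seq[20_000:]]
        draft = GenomeRecord("d", [("p2", pieces[1]), ("p3", pieces[2]), ("p1", pieces[0])])
        ordered, unplaced = order_contigs(draft, ref)
        assert [cid for cid, _ in ordered.contigs] == ["p1", "p2", "p3"]
        assert unplaced == []

    def test_reverse_complemented_contig_flipped(self):
        rng = np.random.default_rng(233)
        ref_seq = random_genome(rng, 20_000)
        ref = GenomeRecord("ref", [("r1", ref_seq)])
        draft = GenomeRecord(
            "d",
            [("p1", ref_seq[:10_000]), ("p2", reverse_complement(ref_seq[10_000:]))],
        )
        ordered, _ = order_contigs(draft, ref)
        assert ordered.sequence("p2") == ref_seq[10_000:]

    def test_unrelated_contig_appended_unplaced(self):
        rng = np.random.default_rng(239)
        ref_seq = random_genome(rng, 20_000)
        ref = GenomeRecord("ref", [("r1", ref_seq)])
        draft = GenomeRecord(
            "d", [("junk", random_genome(rng, 5_000)), ("p1", ref_seq[:10_000])]
        )
        ordered, unplaced = order_contigs(draft, ref)
        assert unplaced == ["junk"]
        assert [cid for cid, _ in ordered.contigs] == ["p1", "junk"]
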