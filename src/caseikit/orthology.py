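"""Orthogroup inference, pangenome statistics and marker selection.

One similarity backbone serves two published parameterizations: orthogroups
are connected components of the all-vs-all protein similarity graph after
pruning weak edges (normalized score < 0.5), and single-copy core markers are
the orthogroups that are single copy in at least 96% of genomes with a
within-group minimum pairwise identity of 70%.  Core orthogroups are those
present (>= 1 member) in strictly more than 95% of the genomes.

Proteomes are plain ``{genome_id: {gene_id: protein}}`` mappings; every gene
ends up in exactly one orthogroup (unmatched genes become singletons).
"""

from __future__ import annotations

import itertools
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import local_align, align_score

Proteomes = dict[str, dict[str, str]]


@dataclass
class SimilarityEdge:
    protein_a: tuple[str, str]  # (genome, gene)
    protein_b: tuple[str, str]
    identity: float
    coverage: float
    normalized_score: float


@dataclass
class OrthogroupTable:
    """orthogroup -> {genome: [gene ids]}, with a derived count matrix."""

    members: dict[str, dict[str, list[str]]]
    genome_ids: list[str]

    def counts(self) -> pd.DataFrame:
        data = {
            og: {g: len(self.members[og].get(g, [])) for g in self.genome_ids}
            for og in self.members
        }
        return pd.DataFrame(data, index=self.genome_ids).fillna(0).astype(int)

    def presence(self, og: str) -> int:
        return sum(1 for g in self.members[og].values() if g)

    @property
    def n_orthogroups(self) -> int:
        return len(self.members)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("orthogroup_id\tgenome\tgene_id\n")
            for og in sorted(self.members):
                for genome in sorted(self.members[og]):
                    for gene in self.members[og][genome]:
                        fh.write(f"{og}\t{genome}\t{gene}\n")


@dataclass
class PangenomeSummary:
    n_genomes: int
    avg_genes_per_genome: float
    sd_genes_per_genome: float
    avg_orthogroups_per_genome: float
    sd_orthogroups_per_genome: float
    n_core: int
    n_accessory: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class MarkerSet:
    orthogroup_ids: list[str]
    genes: dict[str, dict[str, str]]  # og -> genome -> gene_id
    presence_fraction: dict[str, float]
    min_identity: dict[str, float]


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(
    proteomes: Proteomes,
    floor_id: float = 50.0,
    floor_cov: float = 0.50,
    prefilter_k: int = 5,
    prefilter_min_shared: int = 2,
) -> list[SimilarityEdge]:
    """Smith–Waterman similarity edges between all protein pairs.

    A shared-k-mer prefilter (k = 5, >= 2 shared) limits alignment to
    plausible homolog pairs; an edge is kept when identity >= floor_id and the
    coverage of the shorter protein >= floor_cov.  normalized_score is the raw
    score divided by the self-score of the shorter protein, so identical
    proteins score 1.0.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least 2 proteomes")
    for genome, prots in proteomes.items():
        if not prots:
            raise ValueError(f"empty proteome: {genome}")
    keys: list[tuple[str, str]] = [
        (genome, gene) for genome, prots in proteomes.items() for gene in prots
    ]
    seqs = [proteomes[g][p] for g, p in keys]
    # self-score of a sequence under BLOSUM62 is the sum of its diagonal
    # scores (the identity alignment is optimal), no DP needed
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    diag = {a: blosum[a, a] for a in blosum.alphabet}
    self_scores = [sum(diag.get(a, 0.0) for a in s) for s in seqs]

    kmer_owners: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        for km in _kmer_set(s, prefilter_k):
            kmer_owners[km].append(i)
    shared: dict[tuple[int, int], int] = defaultdict(int)
    for owners in kmer_owners.values():
        if len(owners) > 1:
            for a, b in itertools.combinations(owners, 2):
                shared[(a, b)] += 1

    edges: list[SimilarityEdge] = []
    for (a, b), n_shared in shared.items():
        if n_shared < prefilter_min_shared:
            continue
        sa, sb = seqs[a], seqs[b]
        short, long_ = (a, b) if len(sa) <= len(sb) else (b, a)
        # the min of the two coverages can never reach the floor when the
        # lengths are too different; and a cheap score-only pass rules out
        # pairs that cannot clear the identity floor before the (costlier)
        # full alignment is retrieved
        if len(seqs[short]) / len(seqs[long_]) < floor_cov:
            continue
        if self_scores[short] <= 0:
            continue
        if align_score(seqs[short], seqs[long_]) / self_scores[short] < 0.2:
            continue
        hit = local_align(seqs[short], seqs[long_])
        cov = min(
            hit.query_coverage,
            (hit.subject_end - hit.subject_start) / len(seqs[long_]),
        )
        if hit.identity >= floor_id and cov >= floor_cov:
            edges.append(
                SimilarityEdge(
                    protein_a=keys[a],
                    protein_b=keys[b],
                    identity=hit.identity,
                    coverage=cov,
                    normalized_score=hit.score / self_scores[short] if self_scores[short] else 0.0,
                )
            )
    return edges


def infer_orthogroups(
    edges: list[SimilarityEdge],
    proteomes: Proteomes,
    min_normalized_score: float = 0.5,
) -> OrthogroupTable:
    """Orthogroups as connected components of the pruned similarity graph.

    Edges below ``min_normalized_score`` are pruned; components get
    deterministic ids ordered by their lexicographically smallest member.
    """
    keys = [(genome, gene) for genome, prots in proteomes.items() for gene in prots]
    index = {k: i for i, k in enumerate(keys)}
    parent = list(range(len(keys)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        if e.normalized_score >= min_normalized_score:
            parent[find(index[e.protein_a])] = find(index[e.protein_b])

    comps: dict[int, list[tuple[str, str]]] = defaultdict(list)
    for k, i in index.items():
        comps[find(i)].append(k)
    ordered = sorted(comps.values(), key=lambda members: min(members))
    members: dict[str, dict[str, list[str]]] = {}
    width = max(4, len(str(len(ordered))))
    for n, comp in enumerate(ordered):
        og = f"OG{n:0{width}d}"
        per_genome: dict[str, list[str]] = defaultdict(list)
        for genome, gene in sorted(comp):
            per_genome[genome].append(gene)
        members[og] = dict(per_genome)
    return OrthogroupTable(members=members, genome_ids=list(proteomes))


def core_accessory(table: OrthogroupTable, core_frac: float = 0.95) -> PangenomeSummary:
    """Pangenome summary; an orthogroup is core iff present in strictly more
    than ``core_frac`` of the genomes."""
    n_genomes = len(table.genome_ids)
    if n_genomes < 1:
        raise ValueError("need at least one genome")
    counts = table.counts()
    genes_per_genome = counts.sum(axis=1)
    ogs_per_genome = (counts > 0).sum(axis=1)
    presence = (counts > 0).sum(axis=0)
    n_core = int((presence > core_frac * n_genomes).sum())
    return PangenomeSummary(
        n_genomes=n_genomes,
        avg_genes_per_genome=float(genes_per_genome.mean()),
        sd_genes_per_genome=float(genes_per_genome.std(ddof=1)) if n_genomes > 1 else 0.0,
        avg_orthogroups_per_genome=float(ogs_per_genome.mean()),
        sd_orthogroups_per_genome=float(ogs_per_genome.std(ddof=1)) if n_genomes > 1 else 0.0,
        n_core=n_core,
        n_accessory=table.n_orthogroups - n_core,
    )


def single_copy_markers(
    table: OrthogroupTable,
    proteomes: Proteomes,
    edges: list[SimilarityEdge] | None = None,
    min_identity: float = 70.0,
    min_presence: float = 0.96,
) -> MarkerSet:
    """Single-copy core marker orthogroups for concatenated phylogeny.

    An orthogroup qualifies when it has exactly one gene in at least
    ``min_presence`` of the genomes, no genome with more than one copy, and a
    minimum pairwise identity within the group of at least ``min_identity``.
    Pairwise identities are read from the similarity edges when provided
    (missing edge = identity below the all-vs-all floor = disqualifying),
    otherwise computed directly.
    """
    n_genomes = len(table.genome_ids)
    edge_id: dict[frozenset, float] = {}
    if edges is not None:
        for e in edges:
            edge_id[frozenset((e.protein_a, e.protein_b))] = e.identity

    kept: list[str] = []
    genes: dict[str, dict[str, str]] = {}
    presence_fraction: dict[str, float] = {}
    min_id: dict[str, float] = {}
    for og, per_genome in table.members.items():
        copy_counts = [len(v) for v in per_genome.values() if v]
        if any(c > 1 for c in copy_counts):
            continue
        frac = len(copy_counts) / n_genomes
        if frac < min_presence:
            continue
        member_keys = [(g, v[0]) for g, v in per_genome.items() if v]
        worst = 100.0
        ok = True
        for a, b in itertools.combinations(member_keys, 2):
            if edges is not None:
                ident = edge_id.get(frozenset((a, b)))
                if ident is None:
                    ok = False
                    break
            else:
                ident = local_align(proteomes[a[0]][a[1]], proteomes[b[0]][b[1]]).identity
            worst = min(worst, ident)
            if worst < min_identity:
                ok = False
                break
        if not ok:
            continue
        kept.append(og)
        genes[og] = {g: v[0] for g, v in per_genome.items() if v}
        presence_fraction[og] = frac
        min_id[og] = worst
    if not kept:
        warnings.warn("no single-copy marker orthogroups satisfied the thresholds")
    return MarkerSet(
        orthogroup_ids=sorted(kept),
        genes=genes,
        presence_fraction=presence_fraction,
        min_identity=min_id,
    )


def outgroup_augment(
    markers: MarkerSet,
    marker_proteins: dict[str, str],
    outgroup_proteome: dict[str, str],
    outgroup_id: str = "outgroup",
    min_cov: float = 0.75,
    min_id: float = 50.0,
    prefilter_k: int = 5,
) -> dict[str, str | None]:
    """Best outgroup gene per marker, when it clears the similarity floors.

    ``marker_proteins`` maps orthogroup id to a representative protein.
    Returns og -> outgroup gene id (None when no hit passes coverage > min_cov
    and identity > min_id; the supermatrix then carries an all-gap outgroup
    row for that marker).
    """
    if not outgroup_proteome:
        raise ValueError("empty outgroup proteome")
    out_kmers = {gid: _kmer_set(s, prefilter_k) for gid, s in outgroup_proteome.items()}
    result: dict[str, str | None] = {}
    for og in markers.orthogroup_ids:
        rep = marker_proteins[og]
        rep_kmers = _kmer_set(rep, prefilter_k)
        best: tuple[float, str] | None = None
        for gid, seq in outgroup_proteome.items():
            if len(rep_kmers & out_kmers[gid]) < 2:
                continue
            hit = local_align(rep, seq)
            if hit.query_coverage > min_cov and hit.identity > min_id:
                if best is None or hit.score > best[0]:
                    best = (hit.score, gid)
        result[og] = best[1] if best else None
    return result
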