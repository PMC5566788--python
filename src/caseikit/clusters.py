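"""Glycosyltransferase cluster rules and serine-rich adhesin analysis.

A gene cluster is *GT-enriched* when it contains three or more
glycosyltransferase genes with at most 5 kb between two successive GTs
(measured end-of-previous to start-of-next; strictly more than 5 kb breaks
the run).  Clusters are matched across genomes by orthogroup-content Jaccard
similarity, and an archetype is called present in a genome when at least 80%
of its orthogroups have a member there; archetypes seen in only one clade are
flagged clade-specific.

Serine-rich repeat (Srr) adhesins are called by length and serine-content
floors plus two diagnostic motifs: the N-terminal export signal KxYKxGKxW and
an LPxTG-like C-terminal anchor (generalized to L-P-x-[TQ]-[GS] to admit the
rare LPQTS variant).  Frameshifts relative to an intact homolog are detected
from non-multiple-of-3 indels in a global alignment, with the homopolymer
context reported; partial gene copies can be stitched into a consensus by
majority vote over a fragment alignment.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .align import global_align_cigar, infix_align
from .genome_io import GenomeRecord, GeneCall, reverse_complement
from .screen import FeatureCall

GT_FAMILIES = {"GT2", "GT4", "GT8", "GT83", "gt_priming"}

N_MOTIF_PATTERN = re.compile(r"K.YK.GK.W")  # KxYKxGKxW export signal
C_ANCHOR_PATTERN = re.compile(r"LP.[TQ][GS]")
C_ANCHOR_STRICT = re.compile(r"LP.TG")


@dataclass
class GtCluster:
    genome_id: str
    contig_id: str
    gt_gene_ids: list[str]
    gt_families: list[str]
    member_gene_ids: list[str]  # all genes inside the span, in coordinate order
    start: int
    end: int
    gaps: list[int]  # bp between successive GTs
    label: str | None = None
    orthogroups: set[str] = field(default_factory=set)


@dataclass
class SrrCall:
    genome_id: str
    gene_id: str
    length_bp: int
    serine_fraction: float
    n_motif: int | None  # 1-based position, None if absent
    c_motif: str | None  # matched anchor sequence, None if absent
    intact: bool
    defect: str | None = None  # frameshift | truncation | contig_break


@dataclass
class FrameshiftCall:
    position: int  # 1-based position in the intact homolog
    type: str  # insertion | deletion
    length: int
    homopolymer_base: str | None
    homopolymer_run: int
    effect: str  # n_truncation | internal_split

    def __post_init__(self) -> None:
        assert self.length % 3 != 0


def find_gt_clusters(
    gene_calls: list[GeneCall],
    feature_calls: list[FeatureCall],
    min_gts: int = 3,
    max_gap: int = 5000,
    genome_id: str = "",
) -> list[GtCluster]:
    """Maximal runs of GT genes with inter-GT gaps <= max_gap, kept when they
    contain >= min_gts GTs.  Non-GT genes inside the span are recorded as
    cluster members."""
    gt_family: dict[str, str] = {}
    for fc in feature_calls:
        if fc.family in GT_FAMILIES:
            gt_family[fc.gene_id] = fc.family
    by_contig: dict[str, list[GeneCall]] = defaultdict(list)
    for c in gene_calls:
        by_contig[c.contig_id].append(c)
    clusters: list[GtCluster] = []
    for contig, calls in by_contig.items():
        calls = sorted(calls, key=lambda c: c.start)
        gts = [c for c in calls if c.gene_id in gt_family]
        if len(gts) < min_gts:
            continue
        run: list[GeneCall] = []
        for gt in gts:
            # gap = intervening bases between successive GT genes
            if run and gt.start - run[-1].end - 1 > max_gap:
                if len(run) >= min_gts:
                    clusters.append(_make_cluster(genome_id, contig, run, calls, gt_family))
                run = []
            run.append(gt)
        if len(run) >= min_gts:
            clusters.append(_make_cluster(genome_id, contig, run, calls, gt_family))
    return clusters


def _make_cluster(genome_id, contig, run, all_calls, gt_family) -> GtCluster:
    start, end = run[0].start, run[-1].end
    inside = [c for c in all_calls if c.start >= start and c.end <= end]
    return GtCluster(
        genome_id=genome_id,
        contig_id=contig,
        gt_gene_ids=[c.gene_id for c in run],
        gt_families=[gt_family[c.gene_id] for c in run],
        member_gene_ids=[c.gene_id for c in sorted(inside, key=lambda c: c.start)],
        start=start,
        end=end,
        gaps=[b.start - a.end - 1 for a, b in zip(run, run[1:])],
    )


def cluster_presence(
    clusters_by_genome: dict[str, list[GtCluster]],
    gene_orthogroups: dict[tuple[str, str], str],
    clades: dict[str, str],
    orthogroup_presence: dict[str, set[str]],
    min_jaccard: float = 0.5,
    min_presence_frac: float = 0.8,
):
    """Match clusters across genomes into archetypes and score their presence.

    Clusters sharing >= min_jaccard orthogroup content merge into one
    archetype (single linkage).  An archetype is present in a genome when at
    least min_presence_frac of its orthogroups have a member there
    (``orthogroup_presence`` maps orthogroup -> set of genomes carrying it);
    an archetype is clade-specific when its presence is confined to one clade.

    Returns (presence DataFrame, clade-specificity dict, archetype members).
    """
    import pandas as pd

    flat: list[GtCluster] = []
    for genome, cl in clusters_by_genome.items():
        for c in cl:
            c.orthogroups = {
                gene_orthogroups[(genome, g)]
                for g in c.member_gene_ids
                if (genome, g) in gene_orthogroups
            }
            flat.append(c)
    n = len(flat)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            a, b = flat[i].orthogroups, flat[j].orthogroups
            if a and b and len(a & b) / len(a | b) >= min_jaccard:
                parent[find(i)] = find(j)
    groups: dict[int, list[GtCluster]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(flat[i])
    archetypes = sorted(groups.values(), key=lambda g: min(c.genome_id for c in g))

    genomes = sorted(clusters_by_genome)
    rows = {}
    specificity: dict[str, str | None] = {}
    members: dict[str, list[GtCluster]] = {}
    for idx, group in enumerate(archetypes):
        label = f"cluster_{idx + 1}"
        ogs = set().union(*(c.orthogroups for c in group))
        for c in group:
            c.label = label
        present = []
        for g in genomes:
            frac = (
                sum(1 for og in ogs if g in orthogroup_presence.get(og, set())) / len(ogs)
                if ogs
                else 0.0
            )
            present.append(frac >= min_presence_frac)
        rows[label] = dict(zip(genomes, present))
        present_clades = {clades[g] for g, p in zip(genomes, present) if p and g in clades}
        specificity[label] = present_clades.pop() if len(present_clades) == 1 else None
        members[label] = group
    return pd.DataFrame(rows).T, specificity, members


# ---------------------------------------------------------------------------
# serine-rich adhesins


def serine_fraction(protein: str) -> float:
    if not protein:
        raise ValueError("empty translation")
    return protein.count("S") / len(protein)


def scan_motifs(
    protein: str,
    n_window: int = 120,
    c_window: int = 60,
    strict_anchor: bool = False,
) -> tuple[int | None, str | None]:
    """(N-motif position, C-anchor sequence) of an Srr candidate.

    The export signal KxYKxGKxW is searched within the first ``n_window``
    residues; the L-P-x-[TQ]-[GS] anchor within the last ``c_window``.
    Positions are 1-based; absent motifs return None.
    """
    n_hit = N_MOTIF_PATTERN.search(protein[:n_window])
    anchor_re = C_ANCHOR_STRICT if strict_anchor else C_ANCHOR_PATTERN
    c_hit = None
    for m in anchor_re.finditer(protein[max(0, len(protein) - c_window) :]):
        c_hit = m  # keep the last (most C-terminal) match
    return (n_hit.start() + 1 if n_hit else None), (c_hit.group(0) if c_hit else None)


def find_srr(
    gene_calls: list[GeneCall],
    genome_id: str = "",
    min_len: int = 2400,
    min_serine: float = 0.10,
    defects: dict[str, str] | None = None,
) -> list[SrrCall]:
    """Serine-rich adhesin candidates: genes over the length and serine floors,
    motif-scanned and flagged intact when both motifs are present.  ``defects``
    optionally annotates known defective copies (gene_id -> defect type);
    genes missing a motif without a recorded defect are flagged 'truncation'.
    """
    out = []
    for c in gene_calls:
        if c.length < min_len or not c.translation:
            continue
        frac = serine_fraction(c.translation)
        if frac < min_serine:
            continue
        n_pos, anchor = scan_motifs(c.translation)
        intact = n_pos is not None and anchor is not None
        defect = (defects or {}).get(c.gene_id)
        if not intact and defect is None:
            defect = "truncation"
        out.append(
            SrrCall(
                genome_id=genome_id,
                gene_id=c.gene_id,
                length_bp=c.length,
                serine_fraction=frac,
                n_motif=n_pos,
                c_motif=anchor,
                intact=intact,
                defect=None if intact else defect,
            )
        )
    out.sort(key=lambda s: -s.length_bp)
    return out


def _homopolymer_context(seq: str, pos: int) -> tuple[str | None, int]:
    """Base and run length of the homopolymer at 0-based ``pos`` in ``seq``."""
    if not seq:
        return None, 0
    pos = min(max(pos, 0), len(seq) - 1)
    base = seq[pos]
    left = pos
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = pos
    while right + 1 < len(seq) and seq[right + 1] == base:
        right += 1
    return base, right - left + 1


def detect_frameshift(
    region: str,
    intact: str,
    min_identity: float = 60.0,
    n_terminal_fraction: float = 0.10,
) -> FrameshiftCall | None:
    """First frame-disrupting indel of ``region`` relative to its intact
    homolog, or None.

    The two nucleotide sequences are globally aligned; indels whose length is
    not a multiple of 3 are frameshifts.  The call reports the position in
    the intact homolog, the homopolymer context there, and the predicted
    effect: loss of the N-terminus when the shift sits within the first
    ``n_terminal_fraction`` of the gene, an internal split otherwise.
    """
    dist, ops = global_align_cigar(region, intact)
    aligned_cols = sum(n for n, _ in ops)
    identity = 100.0 * (1.0 - dist / aligned_cols) if aligned_cols else 0.0
    if identity < min_identity:
        raise ValueError(f"sequences not comparable (identity {identity:.1f}% < {min_identity}%)")
    # collect indel events, then coalesce events separated by fewer than 10
    # matched columns: an optimal unit-cost alignment may split one 2-bp gap
    # into neighbouring 1-bp gaps
    events: list[list] = []  # [target pos, signed length]
    qpos = tpos = 0
    for n, op in ops:
        if op in "=X":
            qpos += n
            tpos += n
        elif op == "I":  # present in region, absent from the intact homolog
            events.append([tpos, +n])
            qpos += n
        elif op == "D":  # missing from region
            events.append([tpos, -n])
            tpos += n
    merged: list[list] = []
    for pos, ln in events:
        if merged and pos - merged[-1][0] < 10 + abs(merged[-1][1]):
            merged[-1][1] += ln
        else:
            merged.append([pos, ln])
    for pos, net in merged:
        if net == 0 or net % 3 == 0:
            continue
        kind = "insertion" if net > 0 else "deletion"
        if net > 0:
            # gap placement within a repeat is ambiguous: report the longer
            # homopolymer flanking the insertion point
            left = _homopolymer_context(intact, pos - 1)
            right = _homopolymer_context(intact, pos)
            base, run = max(left, right, key=lambda c: c[1])
        else:
            base, run = _homopolymer_context(intact, pos)
        effect = (
            "n_truncation" if pos <= n_terminal_fraction * len(intact) else "internal_split"
        )
        return FrameshiftCall(pos + (0 if net > 0 else 1), kind, abs(net), base, run, effect)
    return None


def reconstruct_consensus(fragments: dict[str, str], min_overlap: int = 50, k: int = 15) -> str:
    """Majority-vote consensus nucleotide sequence from overlapping partial
    gene copies.

    Partial copies (contig-broken or truncated gene sequences from different
    genomes) are laid out against each other by exact shared ``k``-mers: each
    fragment's offset is the modal seed diagonal against the already-placed
    fragments.  Every aligned column then takes the majority base over the
    fragments covering it, ties resolved in favour of the longest fragment.
    Copies are assumed to be indel-free relative to each other (substitutions
    are fine), which holds for same-gene copies across closely related
    strains.  Raises when the fragments do not connect into one layout with
    at least ``min_overlap`` bp of overlap.
    """
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments")
    names = sorted(fragments, key=lambda n: -len(fragments[n]))

    def kmer_positions(seq: str) -> dict[str, int]:
        pos: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            pos.setdefault(seq[i : i + k], i)
        return pos

    kmaps = {n: kmer_positions(fragments[n]) for n in names}
    offsets: dict[str, int] = {names[0]: 0}
    pending = names[1:]
    while pending:
        progressed = False
        for n in list(pending):
            diagonals: list[int] = []
            for placed, off in offsets.items():
                shared = kmaps[n].keys() & kmaps[placed].keys()
                diagonals.extend(
                    off + kmaps[placed][w] - kmaps[n][w] for w in shared
                )
            if len(diagonals) < 3:
                continue
            vals, counts = np.unique(np.array(diagonals), return_counts=True)
            offset = int(vals[np.argmax(counts)])
            # confirm a real overlap of at least min_overlap columns
            span = range(offset, offset + len(fragments[n]))
            overlap = max(
                min(span.stop, offsets[p] + len(fragments[p])) - max(span.start, offsets[p])
                for p in offsets
            )
            if overlap < min_overlap:
                continue
            offsets[n] = offset
            pending.remove(n)
            progressed = True
        if not progressed:
            raise ValueError(
                f"fragments do not overlap: unplaced {sorted(pending)} "
                f"vs placed {sorted(offsets)}"
            )

    origin = min(offsets.values())
    width = max(offsets[n] + len(fragments[n]) for n in names) - origin
    base_idx = {b: i for i, b in enumerate("ACGT")}
    votes = np.zeros((4, width), dtype=np.int32)
    for n in names:
        off = offsets[n] - origin
        for j, b in enumerate(fragments[n]):
            if b in base_idx:
                votes[base_idx[b], off + j] += 1
    consensus = []
    top = votes.max(axis=0)
    arg = votes.argmax(axis=0)
    for col in range(width):
        if top[col] == 0:
            continue
        winners = [b for b in "ACGT" if votes[base_idx[b], col] == top[col]]
        if len(winners) == 1:
            consensus.append("ACGT"[arg[col]])
        else:
            for n in names:  # tie: base of the longest covering fragment
                off = offsets[n] - origin
                if off <= col < off + len(fragments[n]) and fragments[n][col - off] in winners:
                    consensus.append(fragments[n][col - off])
                    break
    return "".join(consensus)


def order_contigs(draft: GenomeRecord, reference: GenomeRecord, anchor_len: int = 10000):
    """Reorder/orient draft contigs by their best anchor position on a
    reference genome; unmapped contigs are appended in input order.

    Returns (reordered GenomeRecord, list of unplaced contig ids).
    """
    if not reference.contigs:
        raise ValueError("empty reference")
    ref_seq = reference.concatenated("N" * 50)
    placed: list[tuple[int, str, str]] = []
    unplaced: list[tuple[str, str]] = []
    for cid, seq in draft.contigs:
        anchor = seq if len(seq) <= anchor_len else seq[
            (len(seq) - anchor_len) // 2 : (len(seq) + anchor_len) // 2
        ]
        fwd = infix_align(anchor, ref_seq)
        rev = infix_align(reverse_complement(anchor), ref_seq)
        best, flip = (fwd, False) if fwd["identity"] >= rev["identity"] else (rev, True)
        if best["location"] is None or best["identity"] < 60.0 or best["coverage"] < 0.5:
            unplaced.append((cid, seq))
        else:
            placed.append((best["location"][0], cid, reverse_complement(seq) if flip else seq))
    placed.sort(key=lambda t: t[0])
    contigs = [(cid, seq) for _, cid, seq in placed] + unplaced
    return (
        GenomeRecord(
            genome_id=draft.genome_id,
            contigs=contigs,
            source_label=draft.source_label,
            clade=draft.clade,
        ),
        [cid for cid, _ in unplaced],
    )
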