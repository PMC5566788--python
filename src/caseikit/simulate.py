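"""Clade-structured synthetic genome sets with planted, truth-tracked features.

The generator emulates the statistical structure of a three-clade bacterial
species group: a common ancestor genome with a gene grid evolves into three
clade ancestors and an outgroup, and each clade ancestor into leaf genomes.
Branch lengths are set so that *pairwise* nucleotide divergence within a
clade equals ``intra_clade_divergence`` (default 0.02, i.e. ANI ≈ 98) and
between clades ``inter_clade_divergence`` (default 0.15, ANI ≈ 85).  Each
clade carries its own GC target (A 46.3%, B 47.75%, C 46.7%): on every
branch the directed A/T↔G/C flips needed to reach the target are folded
into the substitution budget and the remaining substitutions are GC-balanced
(transition-rich, roughly 2:1 over transversions), so leaf GC lands on the
clade target to within a few hundredths of a point.  Substitutions inside
genes avoid creating stop codons and are biased toward synonymous changes
(``syn_fraction``, default 0.7, a crude stand-in for purifying selection);
short indels (geometric lengths) fall only between genes.

Clade-diagnostic content is planted from the synthetic fixture families: an
Fe-Mn SOD in every clade A genome, a 487-aa heme catalase in every clade B
genome, a 269-aa Mn catalase in 7 of 10, a core EPS cluster (priming GT +
GT2 + GT4) in all genomes, and in 6 of 10 clade B genomes an accessory-Sec
locus with the architecture srr1 – GT4 ×2 – GT8 ×3 – SecA2/SecY2/Asp1-3 –
GT4 – unknown gene – srr2.  Optional plans plant homopolymer frameshifts
(a 2-bp deletion near the 5' end of srr1, an A5→A6 insertion near the 5'
end of srr2) and a contig break through srr2.  All outputs are
byte-deterministic given the seed.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from . import _fixtures
from .clusters import FrameshiftCall
from .genome_io import (
    GenomeRecord,
    GeneCall,
    call_orfs,
    reverse_complement,
    write_fasta,
    write_gff3,
    write_protein_fasta,
)

_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOPS = set(_TABLE.stop_codons)
AA_OF = dict(_TABLE.forward_table)
SYN: dict[str, list[str]] = {}
for _codon, _aa in AA_OF.items():
    SYN.setdefault(_aa, []).append(_codon)
for _aa in SYN:
    SYN[_aa].sort()

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_GC = set("GC")

LOCUS_ORDER = [
    "srr1", "GT4", "GT4", "GT8", "GT8", "GT8",
    "secA2", "secY2", "asp1", "asp2", "asp3",
    "GT4", "unknown_cluster_gene", "srr2",
]
LOCUS_ONLY_FAMILIES = {
    "srr1", "srr2", "secA2", "secY2", "asp1", "asp2", "asp3", "unknown_cluster_gene",
}

SPECIES = {"A": "L. paracasei", "B": "L. casei", "C": "L. rhamnosus"}


# ---------------------------------------------------------------------------
# configuration and truth


@dataclass
class FrameshiftPlan:
    family: str
    kind: str  # a_insertion | deletion
    position_fraction: float = 0.038
    del_length: int = 2


@dataclass
class FeaturePlan:
    sod_clades: tuple[str, ...] = ("A",)
    catalase_heme_clades: tuple[str, ...] = ("B",)
    catalase_mn_fraction: float = 0.7  # of clade B genomes
    locus_clade: str = "B"
    locus_fraction: float = 0.6
    # 1-based index within the locus carriers -> frameshift plan
    frameshifts: dict[int, FrameshiftPlan] = field(
        default_factory=lambda: {
            2: FrameshiftPlan(family="srr1", kind="deletion", position_fraction=0.011),
            3: FrameshiftPlan(family="srr2", kind="a_insertion", position_fraction=0.038),
        }
    )
    contig_break_srr2_index: int | None = 4  # 1-based locus-carrier index, None disables


@dataclass
class SimConfig:
    seed: int = 42
    n_per_clade: dict[str, int] = field(default_factory=lambda: {"A": 10, "B": 10, "C": 10})
    genome_length: int = 300_000
    gc_target: dict[str, float] = field(
        default_factory=lambda: {"A": 46.3, "B": 47.75, "C": 46.7}
    )
    intra_clade_divergence: float = 0.02
    inter_clade_divergence: float = 0.15
    outgroup_divergence: float = 0.22  # root -> outgroup branch
    indel_sub_ratio: float = 0.05
    indel_ext_p: float = 0.7
    syn_fraction: float = 0.7
    n_core_genes: int = 60
    n_accessory_genes: int = 30
    accessory_retention: float = 0.85
    n_contigs: int = 1
    features: FeaturePlan = field(default_factory=FeaturePlan)

    def __post_init__(self) -> None:
        assert 0 < self.intra_clade_divergence < 0.75
        assert self.intra_clade_divergence < self.inter_clade_divergence < 0.75
        for c, gc in self.gc_target.items():
            assert 30.0 <= gc <= 70.0, f"clade {c} GC target out of range"

    @property
    def root_gc(self) -> float:
        return float(np.mean(list(self.gc_target.values())))


@dataclass
class TruthTables:
    clades: dict[str, str]
    species: dict[str, str]
    type_strains: dict[str, str]
    gene_orthogroups: dict[str, dict[str, str]]
    families: dict[str, dict[str, list[str]]]
    core_orthogroups: list[str]
    category_map: dict[str, str]
    locus_genomes: list[str]
    locus_order: list[str]
    frameshifts: dict[str, list[dict]]
    contig_breaks: dict[str, list[str]]
    gc_targets: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genomes: dict[str, GenomeRecord]  # ingroup only
    outgroup: GenomeRecord
    gene_calls: dict[str, list[GeneCall]]  # includes the outgroup
    gene_dna: dict[str, dict[str, str]]  # coding-strand gene sequences
    truth: TruthTables

    def proteomes(self, include_outgroup: bool = False) -> dict[str, dict[str, str]]:
        ids = list(self.genomes) + ([self.outgroup.genome_id] if include_outgroup else [])
        return {
            g: {c.gene_id: c.translation for c in self.gene_calls[g] if c.translation}
            for g in ids
        }


# ---------------------------------------------------------------------------
# sequence construction


def reverse_translate(protein: str, gc_target: float, rng: np.random.Generator) -> str:
    """Codon choice tracking a GC target: each residue takes the synonymous
    codon pulling the running GC count toward the target (random among ties)."""
    out = []
    gc_count = 0
    total = 0
    frac = gc_target / 100.0
    for aa in protein:
        codons = SYN[aa]
        if len(codons) == 1:
            codon = codons[0]
        else:
            deficit = frac * (total + 3) - gc_count
            dist = [abs((c.count("G") + c.count("C")) - deficit) for c in codons]
            lo = min(dist)
            best = [c for c, d in zip(codons, dist) if d == lo]
            codon = best[int(rng.integers(len(best)))]
        out.append(codon)
        gc_count += codon.count("G") + codon.count("C")
        total += 3
    return "".join(out)


def _random_intergenic(rng: np.random.Generator, length: int, gc: float) -> str:
    p = gc / 200.0
    return "".join(
        rng.choice(np.array(list("ACGT")), size=length, p=[0.5 - p, p, p, 0.5 - p])
    )


def _pick_stop(rng) -> str:
    return ("TAA", "TGA", "TAG")[int(rng.integers(3))]


@dataclass
class _Slot:
    kind: str  # gene | rna | intergenic | gene_split
    seq: str  # gene/rna: coding strand 5'->3'; intergenic: forward
    strand: str = "+"
    og: str | None = None
    family: str | None = None
    product: str = "hypothetical protein"
    presence: frozenset | str = "core"
    protected: list = field(default_factory=list)  # [(s, e)) on the coding strand
    subcalls: list = field(default_factory=list)  # gene_split: (s0, e0, translation)
    syn_only: bool = False  # adhesins: amino-acid composition is planted truth

    def present_in(self, clade: str) -> bool:
        return self.presence == "core" or clade in self.presence


def _gene_slot(
    rng,
    protein: str,
    og: str,
    gc: float,
    family: str | None = None,
    product: str = "hypothetical protein",
    presence="core",
    strand: str | None = None,
    protect_motifs: bool = False,
    syn_only: bool = False,
) -> _Slot:
    dna = reverse_translate(protein, gc, rng) + _pick_stop(rng)
    protected = [(0, 3), (len(dna) - 3, len(dna))]
    if protect_motifs:
        protected.append((27, 54))  # KxYKxGKxW at residues 10-18
        protected.append((len(dna) - 36, len(dna)))  # C-terminal anchor region
    return _Slot(
        kind="gene",
        seq=dna,
        strand=strand if strand is not None else "+-"[int(rng.integers(2))],
        og=og,
        family=family,
        product=product,
        presence=presence,
        protected=protected,
        syn_only=syn_only,
    )


# ---------------------------------------------------------------------------
# evolution


def _codon_options(codon: str, within: int) -> tuple[list[str], list[str]]:
    """(synonymous, nonsynonymous) replacement bases at codon position
    ``within`` that do not create a stop codon."""
    aa = AA_OF.get(codon)
    old = codon[within]
    syn, nonsyn = [], []
    for b in "ACGT":
        if b == old:
            continue
        nc = codon[:within] + b + codon[within + 1 :]
        if nc in STOPS:
            continue
        (syn if AA_OF.get(nc) == aa else nonsyn).append(b)
    return syn, nonsyn


def _substitute_in_gene(
    seq: list, pos: int, rng, syn_fraction: float, done: set, force_syn: bool = False
) -> bool:
    """One codon-aware substitution event.

    With probability ``syn_fraction`` the event is synonymous: it is applied
    at whichever position of the codon offers a synonymous change (usually
    the third), emulating purifying selection concentrating change at silent
    sites.  Otherwise (or when no silent option exists) a nonsynonymous,
    non-stop change is applied at the sampled position.  Returns False when
    no legal change exists.
    """
    ci = (pos // 3) * 3
    codon = "".join(seq[ci : ci + 3])
    if codon in STOPS or len(codon) < 3:
        return False
    within = pos - ci
    use_pos, pool = None, None
    if rng.random() < syn_fraction:
        for w in (within, 2, 1, 0):  # prefer the sampled position, then scan
            if ci + w in done:
                continue
            syn, _ = _codon_options(codon, w)
            if syn:
                use_pos, pool = w, syn
                break
    if pool is None:
        if force_syn or ci + within in done:
            return False
        syn, nonsyn = _codon_options(codon, within)
        pool = nonsyn or syn
        use_pos = within
        if not pool:
            return False
    old = codon[use_pos]
    weights = np.array([2.0 if _TRANSITION[old] == b else 1.0 for b in pool])
    seq[ci + use_pos] = pool[int(rng.choice(len(pool), p=weights / weights.sum()))]
    done.add(ci + use_pos)
    return True


def _evolve(slots: list[_Slot], q: float, gc_target: float, cfg: SimConfig, rng) -> None:
    """One branch of evolution, in place."""
    if q <= 0:
        return
    skipped = 0  # protected / no-legal-change positions, re-spent intergenically
    for slot in slots:
        if slot.kind not in ("gene", "rna"):
            continue
        n = rng.binomial(len(slot.seq), q)
        if slot.kind == "rna":  # fully protected; budget re-spent intergenically
            skipped += int(n)
            continue
        if n == 0:
            continue
        seq = list(slot.seq)
        done: set[int] = set()
        syn_frac = 1.0 if slot.syn_only else cfg.syn_fraction
        for pos in sorted(rng.choice(len(seq), size=n, replace=False).tolist()):
            if any(s <= pos < e for s, e in slot.protected):
                skipped += 1
                continue
            if not _substitute_in_gene(seq, pos, rng, syn_frac, done, force_syn=slot.syn_only):
                skipped += 1
        slot.seq = "".join(seq)

    inter = [s for s in slots if s.kind == "intergenic"]
    arrays = [bytearray(s.seq.encode()) for s in inter]
    li = sum(len(a) for a in arrays)
    total_len = sum(len(s.seq) for s in slots)
    gc_now = sum(s.seq.count("G") + s.seq.count("C") for s in slots)
    n_flip = round(gc_target / 100.0 * total_len) - gc_now
    n_int = max(int(rng.binomial(li, q)) + skipped, abs(n_flip)) if li else 0
    if n_int:
        n_int = min(n_int, li)
        offsets = np.cumsum([0] + [len(a) for a in arrays])
        flat = np.sort(rng.choice(li, size=n_int, replace=False))
        joined = np.frombuffer(b"".join(bytes(a) for a in arrays), dtype=np.uint8)
        bases = joined[flat]
        is_gc = (bases == ord("G")) | (bases == ord("C"))
        want_gc = n_flip > 0
        donors = flat[~is_gc] if want_gc else flat[is_gc]
        others = flat[is_gc] if want_gc else flat[~is_gc]
        rng.shuffle(donors)
        k_flip = min(abs(n_flip), len(donors))
        new_vals: dict[int, int] = {}
        for p in donors[:k_flip].tolist():
            if want_gc:
                new_vals[p] = ord("G") if rng.random() < 0.5 else ord("C")
            else:
                new_vals[p] = ord("A") if rng.random() < 0.5 else ord("T")
        remaining = np.concatenate([donors[k_flip:], others])
        rb = joined[remaining]
        side_at = remaining[(rb == ord("A")) | (rb == ord("T"))].tolist()
        side_gc = remaining[(rb == ord("G")) | (rb == ord("C"))].tolist()
        ts_at = {ord("A"): ord("G"), ord("T"): ord("C")}
        ts_gc = {ord("G"): ord("A"), ord("C"): ord("T")}
        tv_at = {ord("A"): ord("T"), ord("T"): ord("A")}
        tv_gc = {ord("G"): ord("C"), ord("C"): ord("G")}
        npairs = min(len(side_at), len(side_gc))
        for i in range(npairs):
            if rng.random() < 2.0 / 3.0:  # paired transitions keep net GC at zero
                new_vals[side_at[i]] = ts_at[int(joined[side_at[i]])]
                new_vals[side_gc[i]] = ts_gc[int(joined[side_gc[i]])]
            else:
                new_vals[side_at[i]] = tv_at[int(joined[side_at[i]])]
                new_vals[side_gc[i]] = tv_gc[int(joined[side_gc[i]])]
        for p in side_at[npairs:]:
            new_vals[p] = tv_at[int(joined[p])]
        for p in side_gc[npairs:]:
            new_vals[p] = tv_gc[int(joined[p])]
        for p, v in new_vals.items():
            si = int(np.searchsorted(offsets, p, side="right")) - 1
            arrays[si][p - offsets[si]] = v
        for s, a in zip(inter, arrays):
            s.seq = a.decode()

    n_ind = rng.binomial(li, q * cfg.indel_sub_ratio) if li else 0
    for _ in range(int(n_ind)):
        s = inter[int(rng.integers(len(inter)))]
        if len(s.seq) < 20:
            continue
        pos = int(rng.integers(5, len(s.seq) - 5))
        length = int(rng.geometric(cfg.indel_ext_p))
        if rng.random() < 0.5:
            s.seq = s.seq[:pos] + _random_intergenic(rng, length, gc_target) + s.seq[pos:]
        else:
            s.seq = s.seq[:pos] + s.seq[pos + length :]


# ---------------------------------------------------------------------------
# frameshift planting


def plant_frameshift(dna: str, plan: FrameshiftPlan, rng) -> tuple[str, FrameshiftCall]:
    """Apply one frame-disrupting indel to a coding-strand gene sequence.

    ``a_insertion`` finds (or creates, codon-aligned from K/N codons) a run of
    five A near the planned position and inserts one extra A; ``deletion``
    removes ``del_length`` bases.  Positions in the returned truth call are
    1-based in the intact input sequence."""
    target = int(plan.position_fraction * len(dna))
    if plan.kind == "a_insertion":
        window = dna[max(0, target - 300) : target + 300]
        m = re.search("A{5,}", window)
        if m:
            run_start = max(0, target - 300) + m.start()
            run_len = m.end() - m.start()
        else:
            run_start = ((target // 3) + 1) * 3
            dna = dna[:run_start] + "AAAAA" + dna[run_start + 5 :]
            run_len = 5
            while run_start + run_len < len(dna) and dna[run_start + run_len] == "A":
                run_len += 1
        mutated = dna[:run_start] + "A" + dna[run_start:]
        effect = "n_truncation" if run_start <= 0.10 * len(dna) else "internal_split"
        return mutated, FrameshiftCall(
            position=run_start + 1,
            type="insertion",
            length=1,
            homopolymer_base="A",
            homopolymer_run=run_len,
            effect=effect,
        )
    if plan.kind == "deletion":
        if plan.del_length % 3 == 0:
            raise ValueError("planned deletion length must not be a multiple of 3")
        pos = max(57, target)  # clear of the start codon and signal-motif window
        mutated = dna[:pos] + dna[pos + plan.del_length :]
        base, run = dna[pos], 1
        j = pos
        while j + 1 < len(dna) and dna[j + 1] == base:
            run += 1
            j += 1
        effect = "n_truncation" if pos <= 0.10 * len(dna) else "internal_split"
        return mutated, FrameshiftCall(
            position=pos + 1,
            type="deletion",
            length=plan.del_length,
            homopolymer_base=base,
            homopolymer_run=run,
            effect=effect,
        )
    raise ValueError(f"unknown frameshift kind {plan.kind!r}")


def _reannotate_split(slot: _Slot) -> None:
    """Replace a frameshifted gene by the ORFs its mutated sequence actually
    supports (up to the two longest on the original orientation)."""
    probe = GenomeRecord(genome_id="probe", contigs=[("c", slot.seq)])
    orfs = [c for c in call_orfs(probe, min_len=300) if c.strand == "+"]
    orfs.sort(key=lambda c: -c.length)
    slot.kind = "gene_split"
    slot.subcalls = [(c.start - 1, c.end, c.translation) for c in sorted(orfs[:2], key=lambda c: c.start)]


# ---------------------------------------------------------------------------
# root construction


def _build_root(cfg: SimConfig, rng) -> tuple[list[_Slot], dict[str, str]]:
    gc0 = cfg.root_gc
    prots = _fixtures.family_proteins()
    category: dict[str, str] = {}

    def spacer(n: int | None = None) -> _Slot:
        return _Slot(
            kind="intergenic",
            seq=_random_intergenic(rng, n or int(rng.integers(100, 200)), gc0),
        )

    ordinary: list[_Slot] = []
    for i in range(cfg.n_core_genes):
        og = f"tOG{i:04d}"
        prot = _fixtures._random_protein(rng, int(rng.integers(200, 400)))
        ordinary.append(_gene_slot(rng, prot, og, gc0))
        category[og] = str(rng.choice(list("DJEFHIKLNPQTV")))
    presence_options = [frozenset("A"), frozenset("B"), frozenset("C"), frozenset("BC")]
    presence_cats = {frozenset("A"): "V", frozenset("B"): "C",
                     frozenset("C"): "G", frozenset("BC"): "M"}
    for i in range(cfg.n_accessory_genes):
        og = f"tOGa{i:04d}"
        pres = presence_options[int(rng.choice(4, p=[0.3, 0.2, 0.25, 0.25]))]
        prot = _fixtures._random_protein(rng, int(rng.integers(200, 400)))
        ordinary.append(_gene_slot(rng, prot, og, gc0, presence=pres))
        category[og] = presence_cats[pres]
    order = rng.permutation(len(ordinary))
    ordinary = [ordinary[i] for i in order]

    feature_cats = {"catalase_heme": "O", "catalase_mn": "O", "sod_fe_mn": "O",
                    "secA2": "U", "secY2": "U", "asp1": "U", "asp2": "U", "asp3": "U",
                    "srr1": "U", "srr2": "U", "unknown_cluster_gene": "S"}

    def feature(fam, presence, strand=None, gc=gc0, protect=False) -> _Slot:
        og = f"tOG_{fam}"
        category.setdefault(og, feature_cats.get(fam, "M"))
        return _gene_slot(
            rng, prots[fam], og, gc,
            family=fam, product=_fixtures.PRODUCT_STRINGS[fam],
            presence=presence, strand=strand, protect_motifs=protect,
            syn_only=fam.startswith("srr"),
        )

    b_gc = cfg.gc_target.get("B", gc0)
    a_gc = cfg.gc_target.get("A", gc0)
    B, A = frozenset("B"), frozenset("A")

    slots: list[_Slot] = []

    def block(items: list[_Slot]) -> None:
        for it in items:
            slots.append(it)
            slots.append(spacer())

    n = len(ordinary)
    block(ordinary[: n // 5])
    slots.append(
        _Slot(kind="rna", seq=_fixtures.reference_16s()["L. paracasei"], og="tOG_16S",
              family="rrna_16s", product="16S ribosomal RNA", presence="core",
              protected=[(0, 10**9)])
    )
    slots.append(spacer())
    block(ordinary[n // 5 : 2 * n // 5])
    # core EPS/CPS cluster: priming GT + GT2 + GT4, tight spacing
    for fam in ("gt_priming", "GT2", "GT4"):
        slots.append(feature(fam, "core", "+"))
        slots.append(spacer(150))
    block(ordinary[2 * n // 5 : 3 * n // 5])
    # clade-B accessory-Sec / GT-rich locus, tight spacing
    for fam in LOCUS_ORDER:
        slot = feature(fam, B, "-" if fam == "GT8" else "+", b_gc,
                       protect=fam.startswith("srr"))
        if fam == "srr2":
            # conserved A5 homopolymer near the 5' end: the frameshift
            # hotspot all copies share (two lysine codons, no stop risk)
            p = 840
            slot.seq = slot.seq[:p] + "AAAAA" + slot.seq[p + 5 :]
            slot.protected.append((p - 3, p + 8))
        slots.append(slot)
        slots.append(spacer(120))
    block(ordinary[3 * n // 5 : 4 * n // 5])
    slots.append(feature("sod_fe_mn", A, gc=a_gc))
    slots.append(spacer())
    slots.append(feature("catalase_heme", B, gc=b_gc))
    slots.append(spacer())
    slots.append(feature("catalase_mn", B, gc=b_gc))
    slots.append(spacer())
    block(ordinary[4 * n // 5 :])

    used = sum(len(s.seq) for s in slots)
    filler = max(1000, cfg.genome_length - used)
    slots.append(_Slot(kind="intergenic", seq=_random_intergenic(rng, filler, gc0)))
    return slots, category


# ---------------------------------------------------------------------------
# genome emission


def _emit_genome(
    genome_id: str,
    slots: list[_Slot],
    clade: str | None,
    species: str | None,
    n_contigs: int,
    break_in_family: str | None = None,
) -> tuple[GenomeRecord, list[GeneCall], dict[str, str], dict[str, str], list[str]]:
    """Linearize slots into contigs and gene calls.

    Returns (genome, calls, coding gene sequences, gene -> truth orthogroup,
    gene ids interrupted by a contig break)."""
    fwd_seqs: list[str] = []
    slot_offsets: list[int] = []
    offset = 0
    for s in slots:
        slot_offsets.append(offset)
        fwd = s.seq if (s.kind in ("intergenic", "rna") or s.strand == "+") else reverse_complement(s.seq)
        fwd_seqs.append(fwd)
        offset += len(fwd)
    total = offset

    breaks: list[int] = []
    if n_contigs > 1:
        inter_mid = [
            off + len(f) // 2
            for s, off, f in zip(slots, slot_offsets, fwd_seqs)
            if s.kind == "intergenic" and len(f) >= 120
        ]
        if inter_mid:
            idx = np.linspace(0, len(inter_mid) - 1, min(n_contigs - 1, len(inter_mid)))
            breaks = sorted({inter_mid[int(i)] for i in idx})
    if break_in_family is not None:
        for s, off, f in zip(slots, slot_offsets, fwd_seqs):
            if s.kind in ("gene", "gene_split") and s.family == break_in_family:
                breaks.append(off + len(f) // 2)
        breaks = sorted(set(breaks))
    boundaries = [0] + breaks + [total]

    def contig_of(pos: int) -> int:
        return int(np.searchsorted(boundaries, pos, side="right")) - 1

    calls: list[GeneCall] = []
    gene_dna: dict[str, str] = {}
    gene_og: dict[str, str] = {}
    broken: list[str] = []
    gidx = 0
    for s, off, fwd in zip(slots, slot_offsets, fwd_seqs):
        if s.kind in ("intergenic", "rna"):
            continue
        if s.kind == "gene":
            pieces = [(0, len(fwd), None)]
        else:  # gene_split: subcall coords are on the coding strand
            pieces = []
            for (rs, re_, tr) in s.subcalls:
                if s.strand == "+":
                    pieces.append((rs, re_, tr))
                else:
                    pieces.append((len(fwd) - re_, len(fwd) - rs, tr))
            pieces.sort()
        for (s0, e0, tr) in pieces:
            gstart, gend = off + s0, off + e0
            cs, ce = contig_of(gstart), contig_of(gend - 1)
            if cs == ce:
                sub = [(gstart, gend, tr, False)]
            else:  # interrupted by a contig break; trim both sides to codon length
                cut = boundaries[cs + 1]
                sub = [
                    (gstart, gstart + ((cut - gstart) // 3) * 3, None, True),
                    (cut, cut + ((gend - cut) // 3) * 3, None, True),
                ]
            for (ps, pe, tr_piece, is_broken) in sub:
                if pe - ps < 90:
                    continue
                gene_id = f"{genome_id}_g{gidx:04d}"
                gidx += 1
                fwd_piece = fwd[ps - off : pe - off]
                coding = fwd_piece if s.strand == "+" else reverse_complement(fwd_piece)
                if tr_piece is not None:
                    translation = tr_piece
                else:
                    body = coding[:-3] if coding[-3:] in STOPS else coding
                    translation = str(Seq(body).translate(table=11)).replace("*", "X")
                c0 = boundaries[contig_of(ps)]
                calls.append(
                    GeneCall(
                        gene_id=gene_id,
                        contig_id=f"{genome_id}_c{contig_of(ps) + 1}",
                        start=ps - c0 + 1,
                        end=pe - c0,
                        strand=s.strand,
                        length=pe - ps,
                        translation=translation,
                        product=s.product,
                    )
                )
                gene_dna[gene_id] = coding
                gene_og[gene_id] = s.og or gene_id
                if is_broken:
                    broken.append(gene_id)

    full = "".join(fwd_seqs)
    contigs = [
        (f"{genome_id}_c{i + 1}", full[boundaries[i] : boundaries[i + 1]])
        for i in range(len(boundaries) - 1)
        if boundaries[i + 1] > boundaries[i]
    ]
    genome = GenomeRecord(genome_id=genome_id, contigs=contigs, source_label=species, clade=clade)
    calls.sort(key=lambda c: (c.contig_id, c.start))
    return genome, calls, gene_dna, gene_og, broken


# ---------------------------------------------------------------------------
# the generator


def simulate_group(cfg: SimConfig | None = None) -> SimulatedDataset:
    """Generate the full clade-structured dataset with truth tables."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    root, category = _build_root(cfg, rng)

    q_clade = (cfg.inter_clade_divergence - cfg.intra_clade_divergence) / 2.0
    q_leaf = cfg.intra_clade_divergence / 2.0
    plan = cfg.features
    clades = sorted(cfg.n_per_clade)

    clade_slots: dict[str, list[_Slot]] = {}
    for clade in clades:
        slots = [copy.deepcopy(s) for s in root if s.present_in(clade)]
        for s in slots:
            if s.kind == "rna" and clade in SPECIES:
                s.seq = _fixtures.species_16s(clade)
        _evolve(slots, q_clade, cfg.gc_target[clade], cfg, rng)
        clade_slots[clade] = slots

    out_slots = [
        copy.deepcopy(s)
        for s in root
        if s.kind == "intergenic" or (s.presence == "core" and s.family in (None, "rrna_16s"))
    ]
    for s in out_slots:
        if s.kind == "rna":
            s.seq = _fixtures.reference_16s()["L. nasuensis"]
    _evolve(out_slots, cfg.outgroup_divergence, cfg.root_gc, cfg, rng)

    genomes: dict[str, GenomeRecord] = {}
    gene_calls: dict[str, list[GeneCall]] = {}
    gene_dna: dict[str, dict[str, str]] = {}
    truth_og: dict[str, dict[str, str]] = {}
    families: dict[str, dict[str, list[str]]] = {}
    clade_of: dict[str, str] = {}
    species_of: dict[str, str] = {}
    type_strains: dict[str, str] = {}
    frameshifts: dict[str, list[dict]] = {}
    contig_breaks: dict[str, list[str]] = {}
    locus_genomes: list[str] = []

    n_locus = round(plan.locus_fraction * cfg.n_per_clade.get(plan.locus_clade, 0))
    n_cat_mn = round(plan.catalase_mn_fraction * cfg.n_per_clade.get("B", 0))

    for clade in clades:
        for i in range(cfg.n_per_clade[clade]):
            gid = f"{clade}{i + 1:02d}"
            clade_of[gid] = clade
            species_of[gid] = SPECIES.get(clade, f"species {clade}")
            if i == 0:
                type_strains[gid] = species_of[gid]
            is_locus = clade == plan.locus_clade and i < n_locus
            if is_locus:
                locus_genomes.append(gid)
            keep: list[_Slot] = []
            for s in clade_slots[clade]:
                if s.family is not None:
                    if s.family == "catalase_mn" and not (clade == "B" and i < n_cat_mn):
                        continue
                    is_locus_slot = isinstance(s.presence, frozenset) and (
                        s.family in LOCUS_ONLY_FAMILIES
                        or (s.family in ("GT4", "GT8") and s.presence == frozenset(plan.locus_clade))
                    )
                    if is_locus_slot and not is_locus:
                        continue
                elif isinstance(s.presence, frozenset) and s.kind == "gene":
                    if rng.random() > cfg.accessory_retention:
                        continue
                keep.append(copy.deepcopy(s))
            _evolve(keep, q_leaf, cfg.gc_target[clade], cfg, rng)

            if is_locus:
                fs_plan = plan.frameshifts.get(locus_genomes.index(gid) + 1)
                if fs_plan is not None:
                    for s in keep:
                        if s.family == fs_plan.family:
                            s.seq, call = plant_frameshift(s.seq, fs_plan, rng)
                            _reannotate_split(s)
                            frameshifts.setdefault(gid, []).append(
                                {"family": fs_plan.family, **frameshift_as_dict(call)}
                            )
                            break
            break_family = (
                "srr2"
                if is_locus
                and plan.contig_break_srr2_index is not None
                and locus_genomes.index(gid) + 1 == plan.contig_break_srr2_index
                else None
            )
            genome, calls, dna, ogmap, broken = _emit_genome(
                gid, keep, clade, species_of[gid], cfg.n_contigs, break_family
            )
            genomes[gid] = genome
            gene_calls[gid] = calls
            gene_dna[gid] = dna
            truth_og[gid] = ogmap
            if broken:
                contig_breaks[gid] = broken
            fam_of_og = {s.og: s.family for s in keep if s.family}
            fams: dict[str, list[str]] = {}
            for gene, og in ogmap.items():
                fam = fam_of_og.get(og)
                if fam:
                    fams.setdefault(fam, []).append(gene)
            families[gid] = fams

    outg, outg_calls, outg_dna, outg_ogmap, _ = _emit_genome(
        "OUTG", out_slots, None, "L. nasuensis", 1
    )
    gene_calls["OUTG"] = outg_calls
    gene_dna["OUTG"] = outg_dna
    truth_og["OUTG"] = outg_ogmap

    core_ogs = sorted(
        {s.og for s in root if s.kind == "gene" and s.presence == "core"}
    )
    truth = TruthTables(
        clades=clade_of,
        species=species_of,
        type_strains=type_strains,
        gene_orthogroups=truth_og,
        families=families,
        core_orthogroups=core_ogs,
        category_map=category,
        locus_genomes=locus_genomes,
        locus_order=list(LOCUS_ORDER),
        frameshifts=frameshifts,
        contig_breaks=contig_breaks,
        gc_targets=dict(cfg.gc_target),
    )
    return SimulatedDataset(
        config=cfg,
        genomes=genomes,
        outgroup=outg,
        gene_calls=gene_calls,
        gene_dna=gene_dna,
        truth=truth,
    )


def frameshift_as_dict(call: FrameshiftCall) -> dict:
    return {
        "position": call.position,
        "type": call.type,
        "length": call.length,
        "homopolymer_base": call.homopolymer_base,
        "homopolymer_run": call.homopolymer_run,
        "effect": call.effect,
    }


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Emit FASTA + GFF3 + protein FASTA per genome plus the truth JSON."""
    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    for gid, genome in list(ds.genomes.items()) + [(ds.outgroup.genome_id, ds.outgroup)]:
        write_fasta(genome, out / "genomes" / f"{gid}.fasta")
        write_gff3(ds.gene_calls[gid], out / "annotations" / f"{gid}.gff3", genome_id=gid)
        write_protein_fasta(
            {c.gene_id: c.translation for c in ds.gene_calls[gid] if c.translation},
            out / "annotations" / f"{gid}.faa",
        )
    ds.truth.to_json(out / "truth.json")
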