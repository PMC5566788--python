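"""Interest-driven gene screening by three routes.

Genes of interest (catalases, SODs, glycosyltransferases, accessory-Sec
components, 16S rRNA) are detected by the union of three independent routes:

* ``annotation`` — case-insensitive keyword regexes over gene product strings;
* ``reference``  — best local alignment against known family variants, called
  when identity > 50% and coverage > 75%;
* ``hmm``        — profile-HMM Viterbi scan; GT families additionally apply
  the conventional E-value cutoff of 1e-18.

Each gene receives at most one call per family with the winning route's score
recorded; when routes disagree on the subtype (heme vs Mn catalase, Fe-Mn vs
Cu SOD) the reference route wins ties.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from . import _fixtures
from .align import local_align
from .genome_io import GenomeRecord, GeneCall
from .hmmio import ProfileHMM, hmm_scan, profile_from_sequences

FAMILIES = (
    "catalase_heme",
    "catalase_mn",
    "sod_fe_mn",
    "sod_cu",
    "GT2",
    "GT4",
    "GT8",
    "GT83",
    "gt_priming",
    "secA2",
    "secY2",
    "asp1",
    "asp2",
    "asp3",
    "srr1",
    "srr2",
    "rrna_16s",
)

GT_FAMILIES = set(_fixtures.GT_FAMILIES)

ANNOTATION_PATTERNS = {
    "catalase_heme": r"heme.{0,12}catalase|catalase.{0,12}heme|\bkatA\b",
    "catalase_mn": r"mangan.{0,12}catalase|catalase.{0,12}mangan",
    "sod_fe_mn": r"superoxide dismutase.{0,8}\[?fe|\bsodA\b",
    "sod_cu": r"superoxide dismutase.{0,8}\[?cu",
    "GT2": r"glycosyltransferase family 2",
    "GT4": r"glycosyltransferase family 4",
    "GT8": r"glycosyltransferase family 8",
    "GT83": r"glycosyltransferase family 83",
    "gt_priming": r"priming glycosyltransferase",
    "secA2": r"\bsecA2\b",
    "secY2": r"\bsecY2\b",
    "asp1": r"\basp1\b",
    "asp2": r"\basp2\b",
    "asp3": r"\basp3\b",
    "srr1": r"serine-rich repeat adhesin Srr1",
    "srr2": r"serine-rich repeat adhesin Srr2",
}

# bit-score floor for HMM calls; synthetic single-family profiles give true
# hits scores in the hundreds, unrelated proteins scores near zero
HMM_BITS_FLOOR = 25.0
GT_EVALUE_CUTOFF = 1e-18


@dataclass
class FeatureCall:
    genome_id: str
    gene_id: str
    family: str
    route: str  # annotation | reference | hmm
    score: float = 0.0
    e_value: float | None = None
    identity: float | None = None
    coverage: float | None = None
    routes_agreeing: tuple[str, ...] = ()
    conflict: bool = False


@dataclass
class ScreenConfig:
    """References, HMMs and thresholds per family.

    Defaults are built from the package's synthetic fixture families; a real
    analysis replaces them with curated reference FASTAs and Pfam/dbCAN
    profiles through the same structure.
    """

    references: dict[str, list[str]] = field(default_factory=dict)  # family -> protein seqs
    hmms: dict[str, ProfileHMM] = field(default_factory=dict)
    annotation_patterns: dict[str, str] = field(default_factory=lambda: dict(ANNOTATION_PATTERNS))
    min_identity: float = 50.0
    min_coverage: float = 0.75
    hmm_bits_floor: float = HMM_BITS_FLOOR
    gt_evalue_cutoff: float = GT_EVALUE_CUTOFF
    prefilter_k: int = 5
    prefilter_min_shared: int = 3

    def __post_init__(self) -> None:
        for fam in self.references:
            assert self.references[fam], f"family {fam} has empty reference set"


def default_screen_config(include_srr: bool = False) -> ScreenConfig:
    """Screen configuration over the synthetic fixture families.

    Srr adhesins are screened by composition/motif rules (see
    :mod:`caseikit.clusters`) rather than by similarity, so they are excluded
    from the reference/HMM routes unless requested.
    """
    prots = _fixtures.family_proteins()
    fams = [f for f in prots if include_srr or f not in ("srr1", "srr2")]
    refs = {fam: [prots[fam]] for fam in fams}
    hmms = {
        fam: profile_from_sequences([prots[fam]], name=fam, accession=f"SYN{i:05d}")
        for i, fam in enumerate(fams)
        if fam not in ("srr1", "srr2")  # srr profiles are too long to be useful
    }
    return ScreenConfig(references=refs, hmms=hmms)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def annotation_screen(genome_id: str, calls: list[GeneCall], config: ScreenConfig) -> list[FeatureCall]:
    out = []
    for call in calls:
        for fam, pattern in config.annotation_patterns.items():
            if re.search(pattern, call.product, flags=re.IGNORECASE):
                out.append(
                    FeatureCall(
                        genome_id=genome_id,
                        gene_id=call.gene_id,
                        family=fam,
                        route="annotation",
                        score=1.0,
                    )
                )
    return out


def reference_screen(
    genome_id: str,
    proteins: dict[str, str],
    config: ScreenConfig,
    min_id: float | None = None,
    min_cov: float | None = None,
) -> list[FeatureCall]:
    """Best local alignment per (protein, family); a call is emitted when
    identity > min_id and query coverage (of the reference) > min_cov."""
    min_id = config.min_identity if min_id is None else min_id
    min_cov = config.min_coverage if min_cov is None else min_cov
    out = []
    ref_kmers = {
        fam: [_kmers(r, config.prefilter_k) for r in refs]
        for fam, refs in config.references.items()
    }
    prot_kmers = {gid: _kmers(s, config.prefilter_k) for gid, s in proteins.items()}
    for gid, seq in proteins.items():
        if not seq:
            continue
        for fam, refs in config.references.items():
            best = None
            for ref, rk in zip(refs, ref_kmers[fam]):
                if len(rk & prot_kmers[gid]) < config.prefilter_min_shared:
                    continue
                hit = local_align(ref, seq)  # reference is the query for coverage
                if best is None or hit.score > best.score:
                    best = hit
            if best and best.identity > min_id and best.query_coverage > min_cov:
                out.append(
                    FeatureCall(
                        genome_id=genome_id,
                        gene_id=gid,
                        family=fam,
                        route="reference",
                        score=best.score,
                        identity=best.identity,
                        coverage=best.query_coverage,
                    )
                )
    return out


def hmm_screen(genome_id: str, proteins: dict[str, str], config: ScreenConfig) -> list[FeatureCall]:
    """Profile-HMM route.  A shared-k-mer prescreen against each model's
    consensus limits full Viterbi scans to plausible candidates; GT-family
    calls additionally require E <= the configured cutoff."""
    out = []
    consensus = {
        fam: "".join(_fixtures.AMINO[i] for i in hmm.match_emissions.argmax(axis=1))
        for fam, hmm in config.hmms.items()
    }
    cons_kmers = {fam: _kmers(c, config.prefilter_k) for fam, c in consensus.items()}
    n_targets = max(1, len(proteins))
    for gid, seq in proteins.items():
        if not seq:
            continue
        pk = _kmers(seq, config.prefilter_k)
        for fam, hmm in config.hmms.items():
            if len(pk & cons_kmers[fam]) < config.prefilter_min_shared:
                continue
            bits, e_value, _span = hmm_scan(seq, hmm, n_targets=n_targets)
            if bits < config.hmm_bits_floor:
                continue
            if fam in GT_FAMILIES and e_value > config.gt_evalue_cutoff:
                continue
            out.append(
                FeatureCall(
                    genome_id=genome_id,
                    gene_id=gid,
                    family=fam,
                    route="hmm",
                    score=bits,
                    e_value=e_value,
                )
            )
    return out


_ROUTE_PRIORITY = {"reference": 0, "hmm": 1, "annotation": 2}

_SUBTYPE_GROUPS = [
    {"catalase_heme", "catalase_mn"},
    {"sod_fe_mn", "sod_cu"},
]


def screen_genome(
    genome_id: str,
    calls: list[GeneCall],
    config: ScreenConfig | None = None,
) -> list[FeatureCall]:
    """Union of the three screening routes with per-call provenance.

    Per (gene, family) the best route is kept.  Within a subtype group
    (heme/Mn catalase, Fe-Mn/Cu SOD) a gene keeps only the best-scoring
    family; the reference route wins ties, and genes where routes disagree
    on the subtype carry a conflict flag.
    """
    config = config or default_screen_config()
    proteins = {c.gene_id: c.translation for c in calls if c.translation}
    raw = (
        annotation_screen(genome_id, calls, config)
        + reference_screen(genome_id, proteins, config)
        + hmm_screen(genome_id, proteins, config)
    )
    per_gene_family: dict[tuple[str, str], list[FeatureCall]] = {}
    for c in raw:
        per_gene_family.setdefault((c.gene_id, c.family), []).append(c)

    merged: list[FeatureCall] = []
    for (gid, fam), group in per_gene_family.items():
        group.sort(key=lambda c: _ROUTE_PRIORITY[c.route])
        best = next(
            (c for c in group if c.route == "reference"),
            max(group, key=lambda c: c.score),
        )
        best.routes_agreeing = tuple(sorted({c.route for c in group}))
        merged.append(best)

    # subtype disambiguation: one family per gene within each subtype group
    final: list[FeatureCall] = []
    by_gene: dict[str, list[FeatureCall]] = {}
    for c in merged:
        by_gene.setdefault(c.gene_id, []).append(c)
    for gid, group in by_gene.items():
        for subtypes in _SUBTYPE_GROUPS:
            inside = [c for c in group if c.family in subtypes]
            if len(inside) > 1:
                inside.sort(key=lambda c: (_ROUTE_PRIORITY[c.route], -c.score))
                winner = inside[0]
                winner.conflict = len({c.family for c in inside}) > 1
                group = [c for c in group if c.family not in subtypes] + [winner]
        final.extend(group)
    final.sort(key=lambda c: (c.gene_id, c.family))
    return final


def screen_16s(
    genome: GenomeRecord,
    references: dict[str, str] | None = None,
    min_len: int = 1200,
    min_identity: float = 90.0,
) -> tuple[str, float]:
    """Best-species 16S assignment by local alignment of genome contigs
    against reference 16S sequences (all required to be > min_len nt).

    Returns (species, identity) or ("not a group member", best identity).
    """
    references = references or _fixtures.reference_16s()
    for label, seq in references.items():
        if len(seq) < min_len:
            raise ValueError(f"reference 16S {label!r} shorter than {min_len} nt")
    best_label, best_identity = None, 0.0
    genome_seq = genome.concatenated("N" * 50)
    from .align import infix_align

    for label, ref in references.items():
        res = infix_align(ref, genome_seq)
        if res["coverage"] > 0.8 and res["identity"] > best_identity:
            best_identity = res["identity"]
            best_label = label
    if best_label is None or best_identity < min_identity:
        return "not a group member", best_identity
    return best_label, best_identity


def feature_table(calls: list[FeatureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome": c.genome_id,
                "gene": c.gene_id,
                "family": c.family,
                "route": c.route,
                "score": c.score,
                "e_value": c.e_value,
                "identity": c.identity,
                "coverage": c.coverage,
                "conflict": c.conflict,
            }
            for c in calls
        ]
    )
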