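"""Deterministic synthetic family sequences used for planting and screening.

These are synthetic stand-ins, generated once from a fixed seed, for the
reference proteins and rRNA sequences a real analysis would pull from public
databases: a 487-aa heme-dependent catalase, a 269-aa manganese-dependent
catalase, Fe-Mn and Cu superoxide dismutases, glycosyltransferase families
(GT2/GT4/GT8/GT83 plus a priming GT), the accessory-Sec components
(SecA2, SecY2, Asp1-3), two serine-rich repeat adhesins (srr1: 8,868 bp at
15% serine; srr2: 22,113 bp at 38% serine, with the rare LPQTS anchor
variant) and per-species 16S rRNA variants.  Everything is computed at import
time from a dedicated RNG so the package ships no sequence data files.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .hmmio import AMINO, BACKGROUND

_FIXTURE_SEED = 20170601

N_MOTIF = "KAYKAGKAW"  # matches the KxYKxGKxW export-signal pattern
C_ANCHOR_CANONICAL = "LPKTG"
C_ANCHOR_VARIANT = "LPQTS"

# protein lengths per family (aa, stop codon excluded)
FAMILY_LENGTHS = {
    "catalase_heme": 487,
    "catalase_mn": 269,
    "sod_fe_mn": 202,
    "sod_cu": 160,
    "GT2": 301,
    "GT4": 298,
    "GT8": 305,
    "GT83": 310,
    "gt_priming": 295,
    "secA2": 233,
    "secY2": 230,
    "asp1": 228,
    "asp2": 225,
    "asp3": 222,
    "unknown_cluster_gene": 210,
    "srr1": 2955,  # (2955 + stop) * 3 = 8,868 bp
    "srr2": 7370,  # (7370 + stop) * 3 = 22,113 bp
}

SRR_SERINE_FRACTION = {"srr1": 0.15, "srr2": 0.38}

PRODUCT_STRINGS = {
    "catalase_heme": "heme-dependent catalase",
    "catalase_mn": "manganese-dependent catalase",
    "sod_fe_mn": "superoxide dismutase [Fe-Mn]",
    "sod_cu": "superoxide dismutase [Cu]",
    "GT2": "glycosyltransferase family 2 protein",
    "GT4": "glycosyltransferase family 4 protein",
    "GT8": "glycosyltransferase family 8 protein",
    "GT83": "glycosyltransferase family 83 protein",
    "gt_priming": "priming glycosyltransferase",
    "secA2": "accessory Sec system translocase SecA2",
    "secY2": "accessory Sec system channel protein SecY2",
    "asp1": "accessory Sec system protein Asp1",
    "asp2": "accessory Sec system protein Asp2",
    "asp3": "accessory Sec system protein Asp3",
    "unknown_cluster_gene": "hypothetical protein",
    "srr1": "serine-rich repeat adhesin Srr1",
    "srr2": "serine-rich repeat adhesin Srr2",
    "rrna_16s": "16S ribosomal RNA",
}

GT_FAMILIES = ("GT2", "GT4", "GT8", "GT83", "gt_priming")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    aas = np.array(list(AMINO))
    body = "".join(rng.choice(aas, size=length - 1, p=BACKGROUND / BACKGROUND.sum()))
    return "M" + body  # proteins begin with the initiator methionine


def _srr_protein(rng: np.random.Generator, length: int, serine_fraction: float, anchor: str) -> str:
    """Serine-rich adhesin: N-terminal export motif, serine-enriched body,
    C-terminal cell-wall anchor, with an exact overall serine count."""
    prefix = _random_protein(rng, 9) + N_MOTIF + _random_protein(rng, 21)[1:]
    suffix = anchor + _random_protein(rng, 5)
    body_len = length - len(prefix) - len(suffix)
    target_ser = round(serine_fraction * length)
    fixed_ser = prefix.count("S") + suffix.count("S")
    body_ser = target_ser - fixed_ser
    non_ser = [a for a in AMINO if a != "S"]
    bg = np.array([BACKGROUND[AMINO.index(a)] for a in non_ser])
    body = list(rng.choice(np.array(non_ser), size=body_len, p=bg / bg.sum()))
    pos = rng.choice(body_len, size=body_ser, replace=False)
    for p in pos:
        body[p] = "S"
    return prefix + "".join(body) + suffix


def _mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    bases = "ACGT"
    out = list(seq)
    n_mut = round(rate * len(seq))
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        out[p] = rng.choice([b for b in bases if b != seq[p]])
    return "".join(out)


@lru_cache(maxsize=1)
def family_proteins() -> dict[str, str]:
    """Synthetic reference protein per family, deterministic across runs."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    out: dict[str, str] = {}
    for fam, length in FAMILY_LENGTHS.items():
        if fam in SRR_SERINE_FRACTION:
            anchor = C_ANCHOR_VARIANT if fam == "srr2" else C_ANCHOR_CANONICAL
            out[fam] = _srr_protein(rng, length, SRR_SERINE_FRACTION[fam], anchor)
        else:
            out[fam] = _random_protein(rng, length)
    return out


@lru_cache(maxsize=1)
def reference_16s() -> dict[str, str]:
    """Synthetic per-species 16S rRNA variants (>1,200 nt), plus two
    non-group decoys, standing in for a curated 16S reference database."""
    rng = np.random.default_rng(_FIXTURE_SEED + 1)
    root = "".join(rng.choice(np.array(list("ACGT")), size=1550))
    variants = {}
    for label, rate in [
        ("L. paracasei", 0.005),
        ("L. casei", 0.006),
        ("L. rhamnosus", 0.007),
        ("L. nasuensis", 0.03),
        ("L. plantarum decoy", 0.12),
    ]:
        variants[label] = _mutate_dna(rng, root, rate)
    return variants


def species_16s(clade: str) -> str:
    return reference_16s()[{"A": "L. paracasei", "B": "L. casei", "C": "L. rhamnosus"}[clade]]
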