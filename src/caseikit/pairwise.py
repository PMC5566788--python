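"""Pairwise genome comparison: ANIb, TETRA and the type-strain classifier.

ANIb follows the fragment convention of the JSpecies lineage: the query genome
is cut into consecutive 1,020-bp fragments, each fragment is aligned to the
subject genome, and fragments are kept when the alignment covers more than 70%
of the fragment at more than 30% identity.  ANI is the mean identity of the
kept fragments.  Fragment placement uses an exact 11-mer seed prefilter (the
best-supported diagonal selects a subject window); ``exhaustive=True``
disables the prefilter and scans the whole subject, which is slower but serves
as the reference behaviour in oracle tests.

TETRA is the Pearson correlation between two genomes' 256-element
tetranucleotide z-score vectors.  Counts are taken over both strands, windows
containing N are skipped, and the expected count of a tetranucleotide
w1w2w3w4 is n(w1w2w3)·n(w2w3w4)/n(w2w3) with z = (obs − exp)/sqrt(exp)
(z = 0 where exp = 0).

The species classifier assigns a genome to the species of its best-scoring
type strain when the (two-direction mean) ANI reaches the cutoff; ~95–96% is
the conventional species boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import KmerIndex, encode_kmers, infix_align
from .genome_io import GenomeRecord, reverse_complement

DIAGONAL_MARGIN = 150  # bp of slack around the seeded diagonal window


@dataclass
class TetraProfile:
    """256 tetranucleotide z-scores in lexicographic order over {A,C,G,T}^4."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        assert self.z.shape == (256,)
        assert np.isfinite(self.z).all()


@dataclass
class PairwiseMatrix:
    genome_ids: list[str]
    values: np.ndarray
    metric: str  # ANIB | TETRA | PDIST | BRAYCURTIS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genome_ids, columns=self.genome_ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class SpeciesCall:
    genome_id: str
    best_type_strain: str
    best_ani: float
    assigned_species: str
    margin: float
    tie: bool = False


# ---------------------------------------------------------------------------
# ANIb


def fragment_genome(genome: GenomeRecord, fragment_len: int = 1020, min_tail: int = 100) -> list[str]:
    """Consecutive fragments per contig; a final shorter fragment is kept if >= min_tail bp."""
    frags: list[str] = []
    for _, seq in genome.contigs:
        for i in range(0, len(seq), fragment_len):
            piece = seq[i : i + fragment_len]
            if len(piece) == fragment_len or len(piece) >= min_tail:
                frags.append(piece)
    return frags


class _SubjectIndex:
    """Cached per-subject seeding structure (forward strand only; fragments are
    searched in both orientations)."""

    def __init__(self, genome: GenomeRecord, k: int = 11):
        self.seq = genome.concatenated("N" * 50)  # N spacer keeps alignments within contigs
        self.index = KmerIndex(self.seq, k=k)
        self.k = k


def _best_window(
    index: _SubjectIndex, frag_codes: np.ndarray, frag_len: int, step: int = 1
) -> tuple[int, int] | None:
    qoff, tpos = index.index.seed_positions(frag_codes)
    if len(qoff) == 0:
        return None
    diags = tpos - qoff * step
    # cluster seed diagonals into DIAGONAL_MARGIN-wide bins, anchor on the
    # best-supported bin, then widen to neighbouring diagonals (within 5 kb)
    # so that insertions/deletions between query and subject appear in the
    # alignment as gaps rather than being pushed outside the window
    bins = diags // DIAGONAL_MARGIN
    vals, counts = np.unique(bins, return_counts=True)
    best = vals[np.argmax(counts)]
    sel = np.abs(diags - best * DIAGONAL_MARGIN) <= 5000
    d0 = int(diags[sel].min())
    d1 = int(diags[sel].max())
    lo = max(0, d0 - DIAGONAL_MARGIN)
    hi = min(len(index.seq), d1 + frag_len + DIAGONAL_MARGIN)
    return lo, hi


def _align_fragment(frag: str, index: _SubjectIndex, exhaustive: bool) -> dict | None:
    """Best placement of a fragment on the subject, trying both orientations.

    A strong forward hit (identity > 50% at > 70% coverage) short-circuits the
    reverse-complement attempt: the reverse orientation of the same locus
    cannot outscore it."""
    best = None
    for oriented in (frag, reverse_complement(frag)):
        if exhaustive:
            res = infix_align(oriented, index.seq)
        else:
            # every 3rd k-mer is ample seeding down to ~80% identity
            codes = encode_kmers(oriented, index.k)[::3]
            win = _best_window(index, codes, len(oriented), step=3)
            if win is None:
                continue
            res = infix_align(oriented, index.seq[win[0] : win[1]])
        if res["location"] is not None and (best is None or res["identity"] > best["identity"]):
            best = res
        if best is not None and best["identity"] > 50.0 and best["coverage"] > 0.70:
            break
    return best


def anib(
    query: GenomeRecord,
    subject: GenomeRecord,
    fragment_len: int = 1020,
    min_identity: float = 30.0,
    min_coverage: float = 0.70,
    exhaustive: bool = False,
    _subject_index: "_SubjectIndex | None" = None,
) -> tuple[float | None, pd.DataFrame]:
    """One-directional ANIb of ``query`` against ``subject``.

    Returns (ANI, fragment table).  ANI is None (undefined) when no fragment
    passes the identity/coverage filter.
    """
    index = _subject_index or _SubjectIndex(subject)
    rows = []
    for i, frag in enumerate(fragment_genome(query, fragment_len)):
        res = _align_fragment(frag, index, exhaustive)
        if res is None:
            rows.append((i, len(frag), 0.0, 0.0, False))
            continue
        keep = res["identity"] > min_identity and res["coverage"] > min_coverage
        rows.append((i, len(frag), res["identity"], res["coverage"], keep))
    table = pd.DataFrame(rows, columns=["fragment", "length", "identity", "coverage", "kept"])
    kept = table[table.kept]
    ani = float(kept.identity.mean()) if len(kept) else None
    return ani, table


def anib_matrix(genomes: list[GenomeRecord], **kwargs) -> PairwiseMatrix:
    """Full directional ANIb matrix: entry [i, j] is ANI of query i vs subject j."""
    ids = [g.genome_id for g in genomes]
    n = len(genomes)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    indexes = [_SubjectIndex(g) for g in genomes]
    for j, subj in enumerate(genomes):
        for i, qry in enumerate(genomes):
            if i == j:
                continue
            ani, _ = anib(qry, subj, _subject_index=indexes[j], **kwargs)
            values[i, j] = np.nan if ani is None else ani
    return PairwiseMatrix(ids, values, "ANIB")


def symmetric_ani(matrix: PairwiseMatrix) -> PairwiseMatrix:
    """Mean of the two ANIb directions (used for classification and reporting)."""
    vals = (matrix.values + matrix.values.T) / 2.0
    return PairwiseMatrix(matrix.genome_ids, vals, "ANIB")


# ---------------------------------------------------------------------------
# TETRA

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _kmer_counts(seq_codes: np.ndarray, k: int) -> np.ndarray:
    n = len(seq_codes) - k + 1
    if n <= 0:
        return np.zeros(4**k)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = seq_codes[j : j + n]
        codes = codes * 4 + np.where(col == 255, 0, col)
        bad |= col == 255
    return np.bincount(codes[~bad], minlength=4**k).astype(float)


def tetra_profile(genome: GenomeRecord, min_length: int = 5000) -> TetraProfile:
    """Tetranucleotide z-score profile over all contigs and their reverse complements."""
    total = sum(len(s) - s.count("N") for _, s in genome.contigs)
    if total < min_length:
        raise ValueError(f"{genome.genome_id}: non-N length {total} < {min_length}")
    n2 = np.zeros(16)
    n3 = np.zeros(64)
    n4 = np.zeros(256)
    for _, seq in genome.contigs:
        for s in (seq, reverse_complement(seq)):
            codes = _CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
            n2 += _kmer_counts(codes, 2)
            n3 += _kmer_counts(codes, 3)
            n4 += _kmer_counts(codes, 4)
    idx = np.arange(256)
    left3 = idx >> 2
    right3 = idx & 63
    mid2 = (idx >> 2) & 15
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.where(n2[mid2] > 0, n3[left3] * n3[right3] / n2[mid2], 0.0)
        z = np.where(exp > 0, (n4 - exp) / np.sqrt(exp), 0.0)
    return TetraProfile(z=z)


def tetra_correlation(p: TetraProfile, q: TetraProfile) -> float:
    """Pearson correlation of two z-score profiles."""
    if p.z.std() == 0 or q.z.std() == 0:
        raise ValueError("zero-variance tetranucleotide profile")
    return float(np.corrcoef(p.z, q.z)[0, 1])


def tetra_matrix(genomes: list[GenomeRecord]) -> PairwiseMatrix:
    profiles = [tetra_profile(g) for g in genomes]
    n = len(genomes)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = tetra_correlation(profiles[i], profiles[j])
            values[i, j] = values[j, i] = r
    return PairwiseMatrix([g.genome_id for g in genomes], values, "TETRA")


# ---------------------------------------------------------------------------
# type-strain species classifier


def classify_by_ani(
    genome: GenomeRecord,
    type_strains: list[GenomeRecord],
    cutoff: float = 95.0,
    **anib_kwargs,
) -> SpeciesCall:
    """Assign a species by whole-genome ANI against the group's type strains.

    ANI to each type strain is the mean of the two ANIb directions; the
    best-scoring type strain's species is assigned iff its ANI >= cutoff.
    Ties are broken by larger kept-fragment count, then by type-strain id, and
    flagged.
    """
    if not type_strains:
        raise ValueError("need at least one type strain")
    results = []
    for ts in type_strains:
        fwd, table_fwd = anib(genome, ts, **anib_kwargs)
        rev, _ = anib(ts, genome, **anib_kwargs)
        vals = [v for v in (fwd, rev) if v is not None]
        mean = float(np.mean(vals)) if vals else float("-inf")
        results.append((mean, int(table_fwd.kept.sum()), ts))
    results.sort(key=lambda t: (-t[0], -t[1], t[2].genome_id))
    best_ani, best_frags, best_ts = results[0]
    tie = len(results) > 1 and results[1][0] == best_ani and results[1][1] == best_frags
    assigned = (best_ts.source_label or best_ts.genome_id) if best_ani >= cutoff else "unassigned"
    margin = best_ani - results[1][0] if len(results) > 1 else float("inf")
    return SpeciesCall(
        genome_id=genome.genome_id,
        best_type_strain=best_ts.genome_id,
        best_ani=best_ani,
        assigned_species=assigned,
        margin=margin,
        tie=tie,
    )


def report_near_duplicates(matrix: PairwiseMatrix, threshold: float = 99.99) -> list[list[str]]:
    """Single-linkage groups of near-identical assemblies (possible resequencings)."""
    sym = (matrix.values + matrix.values.T) / 2.0
    n = len(matrix.genome_ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if sym[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(matrix.genome_ids[i])
    return sorted([sorted(g) for g in groups.values() if len(g) > 1])
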