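"""Genome input/output, assembly QC and ORF calling.

Assemblies are handled as :class:`GenomeRecord` objects (ordered contigs over
the ``A C G T N`` alphabet).  Quality control follows the usual draft-assembly
conventions for this group of lactobacilli: assemblies with N75 below 10 kb or
more than 500 undetermined bases per 100 kb are discarded, and a configurable
genome-size window catches hybrid/contaminated assemblies.  A simple
longest-ORF caller stands in for a full annotation pipeline; when a GFF3 +
protein FASTA pair is available those annotations are used verbatim instead.

Coordinates are 1-based inclusive on the forward strand (GFF3 convention);
the strand flag carries orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

VALID_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty file, duplicate headers, bad characters)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One assembly: ordered contigs plus optional labels."""

    genome_id: str
    contigs: list[tuple[str, str]]
    source_label: str | None = None
    clade: str | None = None

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FastaFormatError(f"duplicate contig ids in {self.genome_id}: {dupes}")
        for cid, seq in self.contigs:
            if not seq:
                raise FastaFormatError(f"empty sequence for contig {cid!r} in {self.genome_id}")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise FastaFormatError(
                    f"illegal characters {sorted(bad)} in contig {cid!r} of {self.genome_id}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def concatenated(self, spacer: str = "") -> str:
        return spacer.join(s for _, s in self.contigs)


@dataclass
class QcMetrics:
    total_length: int
    n_contigs: int
    n50: int
    n75: int
    undetermined_per_100kb: float
    gc_percent: float | None


@dataclass
class QcDecision:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # allows `if qc_filter(...)`
        return self.passed


@dataclass
class GeneCall:
    """A protein-coding gene call; nucleotide length includes the stop codon."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    length: int
    translation: str
    product: str = "hypothetical protein"

    def __post_init__(self) -> None:
        if self.length % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {self.length} not divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read a genome FASTA; sequences are upper-cased and U is mapped to T."""
    path = Path(path)
    contigs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        contigs.append((rec.id, _normalize(str(rec.seq))))
    if not contigs:
        raise FastaFormatError(f"no FASTA records in {path}")
    return GenomeRecord(genome_id=genome_id or path.stem, contigs=contigs)


def write_fasta(genome: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA as an ordered id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FastaFormatError(f"duplicate protein id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper().rstrip("*")
    if not out:
        raise FastaFormatError(f"no FASTA records in {path}")
    return out


def write_protein_fasta(proteins: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def assembly_stats(genome: GenomeRecord) -> QcMetrics:
    """N50/N75, undetermined-base density and GC content of one assembly.

    N75 is the length of the contig at which the cumulative length of contigs
    sorted by decreasing length first reaches 75% of the assembly size.  GC is
    computed with N excluded from both numerator and denominator; an all-N
    assembly has undefined GC (None).
    """
    lengths = sorted((len(s) for _, s in genome.contigs), reverse=True)
    total = sum(lengths)
    n50 = n75 = 0
    cum = 0
    for ln in lengths:
        cum += ln
        if not n50 and cum >= 0.5 * total:
            n50 = ln
        if cum >= 0.75 * total:
            n75 = ln
            break
    n_count = gc = acgt = 0
    for _, seq in genome.contigs:
        n_count += seq.count("N")
        g = seq.count("G") + seq.count("C")
        gc += g
        acgt += len(seq) - seq.count("N")
    gc_percent = 100.0 * gc / acgt if acgt else None
    return QcMetrics(
        total_length=total,
        n_contigs=len(lengths),
        n50=n50,
        n75=n75,
        undetermined_per_100kb=100_000 * n_count / total,
        gc_percent=gc_percent,
    )


def qc_filter(
    metrics: QcMetrics,
    n75_min: int = 10_000,
    max_n_per_100kb: float = 500.0,
    size_window: tuple[int, int] = (1_500_000, 4_500_000),
) -> QcDecision:
    """Apply the assembly inclusion filter.

    An assembly fails if N75 < ``n75_min``, if it carries more than
    ``max_n_per_100kb`` undetermined bases per 100 kb, or if its size falls
    outside ``size_window`` (the window catches hybrid assemblies such as the
    5.8-Mb outlier this group's surveys remove by hand).
    """
    reasons: list[str] = []
    if metrics.n75 < n75_min:
        reasons.append(f"N75 {metrics.n75} < {n75_min}")
    if metrics.undetermined_per_100kb > max_n_per_100kb:
        reasons.append(
            f"undetermined bases {metrics.undetermined_per_100kb:.0f}/100kb > {max_n_per_100kb:.0f}"
        )
    lo, hi = size_window
    if not (lo <= metrics.total_length <= hi):
        reasons.append(f"size outlier: {metrics.total_length} outside [{lo}, {hi}]")
    return QcDecision(passed=not reasons, reasons=reasons)


def _orfs_on_strand(seq: str, contig_id: str, strand: str, min_len: int):
    """Maximal ORFs in the three frames of `seq` (already oriented 5'->3')."""
    n = len(seq)
    for frame in range(3):
        start_pending: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start_pending is None and codon in START_CODONS:
                start_pending = pos
            elif codon in STOP_CODONS:
                if start_pending is not None:
                    length = pos + 3 - start_pending
                    if length >= min_len:
                        yield (start_pending, pos + 3, frame)
                start_pending = None


def call_orfs(genome: GenomeRecord, min_len: int = 90) -> list[GeneCall]:
    """Call maximal ORFs on both strands (longest-ORF convention).

    The first start codon (ATG/GTG/TTG) after the preceding in-frame stop opens
    the ORF; the ORF runs to the next in-frame stop, which is included in the
    reported length.  Overlapping calls in the same strand/frame cannot occur by
    construction.  Calls are ordered by (contig, start).
    """
    if min_len < 90 or min_len % 3:
        raise ValueError("min_len must be >= 90 and divisible by 3")
    calls: list[GeneCall] = []
    for cid, seq in genome.contigs:
        found: list[tuple[int, int, str]] = []  # (start0, end0, strand), fwd coords
        for s0, e0, _ in _orfs_on_strand(seq, cid, "+", min_len):
            found.append((s0, e0, "+"))
        rc = reverse_complement(seq)
        for s0, e0, _ in _orfs_on_strand(rc, cid, "-", min_len):
            found.append((len(seq) - e0, len(seq) - s0, "-"))
        found.sort()
        for s0, e0, strand in found:
            sub = seq[s0:e0] if strand == "+" else reverse_complement(seq[s0:e0])
            if "N" in sub:
                continue
            prot = str(Seq(sub[:-3]).translate(table=11))
            calls.append(
                GeneCall(
                    gene_id=f"{cid}_{s0 + 1}_{strand}",
                    contig_id=cid,
                    start=s0 + 1,
                    end=e0,
                    strand=strand,
                    length=e0 - s0,
                    translation=prot,
                )
            )
    calls.sort(key=lambda c: (c.contig_id, c.start))
    return calls


def gene_sequence(genome: GenomeRecord, call: GeneCall) -> str:
    """Forward-strand slice of a gene call, reverse-complemented for '-' calls."""
    seq = genome.sequence(call.contig_id)[call.start - 1 : call.end]
    return seq if call.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# GFF3 + QC table plumbing


def write_gff3(calls: Sequence[GeneCall], path: str | Path, genome_id: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in calls:
            attrs = f"ID={c.gene_id};product={c.product}"
            fh.write(
                f"{c.contig_id}\tcaseikit\tCDS\t{c.start}\t{c.end}\t.\t{c.strand}\t0\t{attrs}\n"
            )


_ATTR_RE = re.compile(r"(\w+)=([^;]*)")


def read_gff3(path: str | Path, proteins: dict[str, str] | None = None) -> list[GeneCall]:
    """Read CDS features from a GFF3 file; translations come from ``proteins``
    when given, otherwise are left empty strings."""
    calls: list[GeneCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "CDS":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            gid = attrs.get("ID", f"{parts[0]}_{parts[3]}_{parts[6]}")
            length = int(parts[4]) - int(parts[3]) + 1
            calls.append(
                GeneCall(
                    gene_id=gid,
                    contig_id=parts[0],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    strand=parts[6],
                    length=length,
                    translation=(proteins or {}).get(gid, ""),
                    product=attrs.get("product", "hypothetical protein"),
                )
            )
    calls.sort(key=lambda c: (c.contig_id, c.start))
    return calls


def qc_table(genomes: Iterable[GenomeRecord]):
    """QC metrics for a set of genomes as a pandas DataFrame (one row each)."""
    import pandas as pd

    rows = []
    for g in genomes:
        m = assembly_stats(g)
        rows.append(
            {
                "genome_id": g.genome_id,
                "total_length": m.total_length,
                "n_contigs": m.n_contigs,
                "n50": m.n50,
                "n75": m.n75,
                "undetermined_per_100kb": m.undetermined_per_100kb,
                "gc_percent": np.nan if m.gc_percent is None else m.gc_percent,
            }
        )
    return pd.DataFrame(rows).set_index("genome_id")
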