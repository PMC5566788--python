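"""Shared alignment primitives.

Two engines back everything in the package:

* :func:`local_align` — optimal Smith–Waterman local alignment with affine
  gaps (Bio.Align.PairwiseAligner), used for protein similarity and for small
  nucleotide comparisons.  Default nucleotide scoring is match +1 /
  mismatch −2 / gap open −4 / gap extend −2; proteins use BLOSUM62 with
  open −11 / extend −1.
* :func:`global_align_cigar` — fast global (Needleman–Wunsch, unit-cost)
  nucleotide alignment via edlib, used where indel structure matters
  (frameshift detection) and as the workhorse inside the ANIb fragment engine.

A sorted-array k-mer index (:class:`KmerIndex`) provides the seed prefilter
used to place genome fragments before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass
class AlignmentHit:
    """A scored local alignment.

    identity is percent matches over aligned columns (gap columns included);
    query_coverage is the fraction of the query spanned by the alignment.
    """

    query_id: str
    subject_id: str
    identity: float
    query_coverage: float
    score: float
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0

    def __post_init__(self) -> None:
        assert 0.0 <= self.identity <= 100.0
        assert 0.0 <= self.query_coverage <= 1.0 + 1e-9


NUC_SCORING = {"match": 1, "mismatch": -2, "open": -4, "extend": -2}


@lru_cache(maxsize=8)
def _nuc_aligner(match: int, mismatch: int, open_: int, extend: int, mode: str):
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = open_
    al.extend_gap_score = extend
    return al

@lru_cache(maxsize=2)
def _prot_aligner(mode: str):
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


def _is_protein(seq: str) -> bool:
    return bool(set(seq) - set("ACGTN"))


def _identity_from_alignment(aln) -> tuple[float, int]:
    counts = aln.counts()  # gaps, identities, mismatches
    cols = counts.gaps + counts.identities + counts.mismatches
    return (100.0 * counts.identities / cols if cols else 0.0), cols


def local_align(
    a: str,
    b: str,
    scoring: dict | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    mode: str = "local",
) -> AlignmentHit:
    """Optimal local (Smith–Waterman, affine-gap) alignment of two sequences.

    Scoring is inferred from the alphabet: nucleotide sequences use the
    ``scoring`` dict (defaults to :data:`NUC_SCORING`), anything else BLOSUM62.
    Ties are broken deterministically by the aligner (first of the co-optimal
    alignments, i.e. smallest start coordinate then shortest alignment).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    prot_a, prot_b = _is_protein(a), _is_protein(b)
    if prot_a != prot_b:
        raise ValueError("alphabet mismatch between query and subject")
    if prot_a:
        aligner = _prot_aligner(mode)
    else:
        s = dict(NUC_SCORING, **(scoring or {}))
        aligner = _nuc_aligner(s["match"], s["mismatch"], s["open"], s["extend"], mode)
    aln = next(iter(aligner.align(a, b)))
    identity, _ = _identity_from_alignment(aln)
    (qs, qe) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    (ss, se) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=identity,
        query_coverage=(qe - qs) / len(a),
        score=float(aln.score),
        query_start=qs,
        query_end=qe,
        subject_start=ss,
        subject_end=se,
    )


def align_score(a: str, b: str, mode: str = "local") -> float:
    """Alignment score only (cheaper than retrieving the alignment)."""
    aligner = _prot_aligner(mode) if _is_protein(a) else _nuc_aligner(
        NUC_SCORING["match"], NUC_SCORING["mismatch"], NUC_SCORING["open"], NUC_SCORING["extend"], mode
    )
    return float(aligner.score(a, b))


# ---------------------------------------------------------------------------
# edlib wrappers


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def global_align_cigar(query: str, target: str) -> tuple[int, list[tuple[int, str]]]:
    """Global unit-cost alignment; returns (edit distance, cigar ops).

    Ops use edlib's extended cigar: '=' match, 'X' mismatch, 'I' insertion in
    the query (absent from target), 'D' deletion from the query.
    """
    res = edlib.align(query, target, mode="NW", task="path")
    return res["editDistance"], list(_cigar_ops(res["cigar"]))


def infix_align(query: str, target: str, max_internal_gap: int = 30) -> dict:
    """Semi-global alignment of the full query inside the target (edlib HW),
    scored the way a local aligner would score its best dense segment.

    Terminal indel runs are trimmed and the alignment is split at internal gap
    runs longer than ``max_internal_gap`` (a local aligner would not bridge
    such gaps); the segment with the most matches is scored.  Returns identity
    over the segment's columns, coverage as segment query columns over query
    length, and the matched target location.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["cigar"]:
        return {"identity": 0.0, "coverage": 0.0, "location": None, "matches": 0, "columns": 0}
    lengths = np.array([n for n, _ in _cigar_ops(res["cigar"])], dtype=np.int64)
    opcodes = np.frombuffer(
        "".join(op for _, op in _cigar_ops(res["cigar"])).encode(), dtype=np.uint8
    )
    col_op = np.repeat(opcodes, lengths)
    # per-column scores, blastn-like 1/-2; the maximal-scoring run is what a
    # local aligner would have reported
    col_score = np.where(col_op == ord("="), 1.0, -2.0)
    csum = np.concatenate(([0.0], np.cumsum(col_score)))
    start_at_min = np.minimum.accumulate(csum[:-1])
    gains = csum[1:] - start_at_min
    end = int(np.argmax(gains))
    if gains[end] <= 0:
        return {"identity": 0.0, "coverage": 0.0, "location": None, "matches": 0, "columns": 0}
    begin = int(np.argmin(csum[: end + 1]))
    seg = col_op[begin : end + 1]
    # coverage comes from the dense segment (what a local aligner would keep);
    # identity is reported over the full alignment after trimming terminal
    # indel runs, so it reflects the overall divergence of the fragment
    qcols = int(np.isin(seg, (ord("="), ord("X"), ord("I"))).sum())
    not_gap = col_op != ord("I")
    not_gap &= col_op != ord("D")
    inner = np.nonzero(not_gap)[0]
    full = col_op[inner[0] : inner[-1] + 1] if len(inner) else col_op[:0]
    matches = int((full == ord("=")).sum())
    columns = int(len(full))
    tcols_before = int(np.isin(col_op[:begin], (ord("="), ord("X"), ord("D"))).sum())
    loc = res["locations"][0] if res["locations"] else None
    if loc is not None and loc[0] is not None:
        loc = (loc[0] + tcols_before, loc[1])
    return {
        "identity": 100.0 * matches / columns if columns else 0.0,
        "coverage": qcols / len(query) if query else 0.0,
        "location": loc,
        "matches": matches,
        "columns": columns,
    }


# ---------------------------------------------------------------------------
# k-mer seeding

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Codes of all k-mers of `seq` (base-4); windows containing N get code 2**63."""
    arr = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = arr[j : j + n]
        codes = codes * np.uint64(4) + np.where(col == 255, 0, col).astype(np.uint64)
        bad |= col == 255
    codes[bad] = np.uint64(1) << np.uint64(63)
    return codes


class KmerIndex:
    """Sorted (code, position) index over one sequence for seed lookup."""

    def __init__(self, seq: str, k: int = 11):
        self.k = k
        self.length = len(seq)
        codes = encode_kmers(seq, k)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.positions = order.astype(np.int64)

    def seed_positions(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query offsets, target positions) of all exact k-mer matches."""
        left = np.searchsorted(self.codes, query_codes, side="left")
        right = np.searchsorted(self.codes, query_codes, side="right")
        counts = right - left
        hit = counts > 0
        if not hit.any():
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qoff = np.repeat(np.nonzero(hit)[0], counts[hit])
        tpos = np.concatenate([self.positions[l:r] for l, r in zip(left[hit], right[hit])])
        return qoff.astype(np.int64), tpos
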