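"""Concatenated-marker distance phylogeny with bootstrap and clade extraction.

Markers are aligned per family (MAFFT), concatenated into a supermatrix with
all-gap blocks for missing taxa, and summarized as uncorrected p-distances
(Jukes–Cantor correction optional).  Tree inference is neighbor joining with
nonparametric bootstrap over supermatrix columns: support of an internal edge
is the percentage of replicate trees containing the same bipartition.

Clades are extracted by rooting with the outgroup and cutting the
well-supported internal edges whose lengths stand out by the largest relative
gap; leaves separated by a cut edge fall into different clades.  This
branch-length-gap heuristic is this package's own formalization of the usual
visual delimitation of deeply separated, internally shallow clades.
"""

from __future__ import annotations

import io
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .pairwise import PairwiseMatrix


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]  # taxon -> concatenated aligned sequence
    partitions: dict[str, tuple[int, int]]  # marker -> (start, end) 1-based inclusive

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        assert len(lengths) == 1, "unequal supermatrix row lengths"
        (self.width,) = lengths

    def marker_block(self, marker: str) -> dict[str, str]:
        s, e = self.partitions[marker]
        return {t: self.rows[t][s - 1 : e] for t in self.taxa}

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.rows[t]}\n")


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports on
    internal edges (stored as internal-node labels)."""

    tree: TreeNode

    def write_newick(self, path) -> None:
        self.tree.write(str(path), format="newick")

    def newick(self) -> str:
        out = io.StringIO()
        self.tree.write(out, format="newick")
        return out.getvalue()

    def bipartitions(self) -> dict[frozenset, tuple[float, float | None]]:
        """Internal-edge bipartitions -> (branch length, support)."""
        all_tips = frozenset(t.name for t in self.tree.tips())
        out: dict[frozenset, tuple[float, float | None]] = {}
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_tips) - 1:
                support = None
                if node.name not in (None, ""):
                    try:
                        support = float(node.name)
                    except ValueError:
                        support = None
                out[_canonical(side, all_tips)] = (node.length or 0.0, support)
        return out


@dataclass
class CladeAssignment:
    clades: dict[str, str]  # genome_id -> clade label
    defining_edges: list[tuple[frozenset, float, float | None]]

    def labels(self, taxa: list[str]) -> list[str]:
        return [self.clades[t] for t in taxa]


def _canonical(side: frozenset, all_tips: frozenset) -> frozenset:
    """Orient a bipartition to the side not containing the reference tip."""
    ref = min(all_tips)
    return frozenset(all_tips - side) if ref in side else side


# ---------------------------------------------------------------------------
# alignment and supermatrix


def progressive_msa(
    seqs: dict[str, str], mafft_args: tuple[str, ...] | None = None
) -> dict[str, str]:
    """Multiple sequence alignment (MAFFT, deterministic).

    The fast progressive mode (FFT-NS-2) is used for ordinary marker-sized
    inputs; very short sequences (< 200 nt) fall back to the exact pairwise
    mode (G-INS-i), where the FFT heuristic is unreliable.  A single sequence
    is returned unchanged; two or more are aligned and returned in input
    order, upper-cased.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return dict(seqs)
    if mafft_args is None:
        short = max(len(s) for s in seqs.values()) < 200
        mafft_args = ("--globalpair", "--maxiterate", "16") if short else ("--retree", "2")
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fasta"
        with open(inp, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
        res = subprocess.run(
            ["mafft", "--quiet", *mafft_args, str(inp)],
            capture_output=True,
            text=True,
            check=True,
        )
    aligned: dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            aligned[name] = ""
        elif name is not None:
            aligned[name] += line.strip().upper()
    return {name: aligned[name] for name in seqs}  # restore input order


def concatenate(alignments: dict[str, dict[str, str]], taxa: list[str]) -> Supermatrix:
    """Concatenate per-marker alignments; missing taxa get all-gap blocks."""
    if not alignments:
        raise ValueError("no marker alignments")
    rows = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for marker in alignments:
        block = alignments[marker]
        widths = {len(s) for s in block.values()}
        assert len(widths) == 1, f"ragged alignment for marker {marker}"
        (w,) = widths
        partitions[marker] = (pos + 1, pos + w)
        pos += w
        for t in taxa:
            rows[t].append(block.get(t, "-" * w))
    return Supermatrix(taxa=taxa, rows={t: "".join(v) for t, v in rows.items()}, partitions=partitions)


def _matrix_array(sm: Supermatrix) -> np.ndarray:
    return np.frombuffer("".join(sm.rows[t] for t in sm.taxa).encode(), dtype=np.uint8).reshape(
        len(sm.taxa), sm.width
    )


_GAP_CODES = frozenset(b"-.NX")


def _pdist_from_array(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    gap = np.isin(arr, np.frombuffer(b"-.NX", dtype=np.uint8))
    dist = np.zeros((n, n))
    for i in range(n):
        both = ~gap[i] & ~gap[i + 1 :]
        comparable = both.sum(axis=1)
        diff = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comparable > 0, diff / np.maximum(comparable, 1), np.nan)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
    return dist


def p_distance(sm: Supermatrix, jukes_cantor: bool = False) -> PairwiseMatrix:
    """Pairwise proportion of differing sites over mutually ungapped columns."""
    if len(sm.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    dist = _pdist_from_array(_matrix_array(sm))
    if np.isnan(dist).any():
        pairs = [
            (sm.taxa[i], sm.taxa[j])
            for i, j in zip(*np.nonzero(np.isnan(np.triu(dist))))
        ]
        raise ValueError(f"no comparable columns for pairs: {pairs}")
    if jukes_cantor:
        capped = np.minimum(dist, 0.7499)
        dist = -0.75 * np.log1p(-4.0 * capped / 3.0)
    return PairwiseMatrix(list(sm.taxa), dist, "PDIST")


# ---------------------------------------------------------------------------
# trees


def nj_tree(D: PairwiseMatrix) -> PhyloTree:
    """Neighbor joining; negative branch lengths are clamped to zero."""
    if len(D.genome_ids) < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(D.values).any():
        raise ValueError("missing distances in matrix")
    dm = DistanceMatrix((D.values + D.values.T) / 2.0, D.genome_ids)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return PhyloTree(tree=tree)


def bootstrap_support(
    sm: Supermatrix, n_reps: int = 100, seed: int = 0, jukes_cantor: bool = False
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    With ``n_reps=0`` the plain tree is returned without supports.  When the
    supermatrix is degenerate (all rows identical) supports are left missing.
    """
    base = nj_tree(p_distance(sm, jukes_cantor=jukes_cantor))
    if n_reps <= 0:
        return base
    arr = _matrix_array(sm)
    degenerate = bool((arr == arr[0]).all())
    all_tips = frozenset(sm.taxa)
    target = {bp: 0 for bp in base.bipartitions()}
    if not degenerate:
        rng = np.random.default_rng(seed)
        for _ in range(n_reps):
            cols = rng.integers(0, sm.width, size=sm.width)
            rep_dist = _pdist_from_array(arr[:, cols])
            if np.isnan(rep_dist).any():
                continue
            rep = nj(DistanceMatrix((rep_dist + rep_dist.T) / 2.0, sm.taxa))
            seen = set()
            for node in rep.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(sm.taxa) - 1:
                    seen.add(_canonical(side, all_tips))
            for bp in target:
                if bp in seen:
                    target[bp] += 1
    for node in base.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(sm.taxa) - 1:
            bp = _canonical(side, all_tips)
            node.name = "" if degenerate else f"{100.0 * target[bp] / n_reps:g}"
    return base


def extract_clades(
    ptree: PhyloTree,
    outgroup_id: str,
    min_support: float = 70.0,
    k: int | None = None,
    type_strain_labels: dict[str, str] | None = None,
    max_cuts: int = 8,
) -> CladeAssignment:
    """Delimit clades by cutting deep, well-supported internal edges.

    The outgroup is removed, internal edges with support >= ``min_support``
    (edges without support are eligible) are sorted by branch length, and the
    cut set is the head of that order up to the largest relative length gap
    (or the ``k-1``... up to ``k`` longest when ``k`` is given).  Leaves whose
    connecting path crosses a cut edge land in different clades.  Clades are
    labelled A, B, C, ... in order of their smallest member, or by the species
    of the type strain they contain when ``type_strain_labels`` is given.
    """
    tree = ptree.tree.copy()
    try:
        og_tip = next(t for t in tree.tips() if t.name == outgroup_id)
    except StopIteration:
        raise ValueError(f"outgroup {outgroup_id!r} not in tree")
    # root at the outgroup pendant edge, then drop the outgroup
    tree = tree.root_at(og_tip.parent) if og_tip.parent is not tree else tree
    og_tip = next(t for t in tree.tips() if t.name == outgroup_id)
    parent = og_tip.parent
    parent.remove(og_tip)
    tree.prune()

    candidates = []  # (length, node, support)
    for node in tree.non_tips(include_self=False):
        tips_below = [t.name for t in node.tips()]
        if not (1 <= len(tips_below) < len(list(tree.tips()))):
            continue
        support = None
        if node.name not in (None, ""):
            try:
                support = float(node.name)
            except ValueError:
                support = None
        if support is not None and support < min_support:
            continue
        candidates.append((node.length or 0.0, node, support))
    candidates.sort(key=lambda t: -t[0])

    if k is not None:
        cut_nodes = {id(n) for _, n, _ in candidates[: max(0, k)]}
    elif candidates:
        # depth contrast: candidate internal edges against the shallow
        # structure, with pendant edges included so that two-member clades
        # (no internal intra-clade edges) still expose the length gap
        tip_lengths = [t.length or 0.0 for t in tree.tips()]
        contrast = sorted(
            [l for l, _, _ in candidates] + tip_lengths, reverse=True
        )[: max_cuts + 3]
        ratios = [
            (contrast[i] / contrast[i + 1]) if contrast[i + 1] > 0 else np.inf
            for i in range(len(contrast) - 1)
        ]
        best_gap = int(np.argmax(ratios))
        if ratios[best_gap] < 2.0:  # no clear depth separation: one clade
            cut_nodes = set()
        else:
            threshold = contrast[best_gap]
            cut_nodes = {
                id(n)
                for l, n, _ in candidates[:max_cuts]
                if l >= threshold - 1e-12
            }
    else:
        cut_nodes = set()

    # group leaves by the set of cut edges above them
    groups: dict[frozenset, list[str]] = {}
    for tip in tree.tips():
        cuts_above = frozenset(
            id(anc) for anc in tip.ancestors() if id(anc) in cut_nodes
        )
        groups.setdefault(cuts_above, []).append(tip.name)
    ordered = sorted(groups.values(), key=min)

    clades: dict[str, str] = {}
    defining = [
        (frozenset(t.name for t in n.tips()), l, s)
        for l, n, s in candidates
        if id(n) in cut_nodes
    ]
    for i, group in enumerate(ordered):
        label = chr(ord("A") + i) if i < 26 else f"clade{i}"
        if type_strain_labels:
            for member in group:
                if member in type_strain_labels:
                    label = type_strain_labels[member]
                    break
        for member in group:
            clades[member] = label
    return CladeAssignment(clades=clades, defining_edges=defining)
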