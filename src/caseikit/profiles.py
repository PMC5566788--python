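"""Per-genome functional-category profiles, distances and ordination.

Orthogroups carry one or more single-letter functional categories (the
COG/eggNOG alphabet; "S" = function unknown).  For a chosen category the
profile of a genome is its orthogroup count vector restricted to that
category; genomes are compared by Bray–Curtis dissimilarity and ordinated by
classical PCoA (double-centering + eigendecomposition).  Category assignment
itself is an input table — the simulator provides a ground-truth map, real
analyses supply one from an external functional annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .orthology import OrthogroupTable
from .pairwise import PairwiseMatrix

CATEGORY_ALPHABET = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass
class CategoryMap:
    """orthogroup_id -> set of category letters (multi-membership allowed)."""

    assignments: dict[str, set[str]]

    def __post_init__(self) -> None:
        for og, cats in self.assignments.items():
            bad = set(cats) - CATEGORY_ALPHABET
            if bad:
                raise ValueError(f"unknown category letters {sorted(bad)} for {og}")

    def orthogroups_in(self, category: str) -> list[str]:
        if category not in CATEGORY_ALPHABET:
            raise ValueError(f"unknown category letter {category!r}")
        return sorted(og for og, cats in self.assignments.items() if category in cats)

    @property
    def categories(self) -> list[str]:
        return sorted({c for cats in self.assignments.values() for c in cats})

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CategoryMap":
        assignments: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                og, cats = line.rstrip("\n").split("\t")[:2]
                assignments[og] = set(cats)
        return cls(assignments)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for og in sorted(self.assignments):
                fh.write(f"{og}\t{''.join(sorted(self.assignments[og]))}\n")


@dataclass
class Ordination:
    coordinates: pd.DataFrame  # genomes x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_dropped: int = 0


def category_profile(table: OrthogroupTable, cat_map: CategoryMap, category: str) -> pd.DataFrame:
    """Genome x orthogroup count matrix restricted to one category."""
    ogs = [og for og in cat_map.orthogroups_in(category) if og in table.members]
    if not ogs:
        raise ValueError(f"no orthogroups mapped to category {category!r}")
    counts = table.counts()
    return counts[ogs]


def category_totals(table: OrthogroupTable, cat_map: CategoryMap) -> pd.DataFrame:
    """Genome x category matrix of orthogroup-occurrence counts."""
    counts = table.counts()
    data = {}
    for cat in cat_map.categories:
        ogs = [og for og in cat_map.orthogroups_in(cat) if og in counts.columns]
        data[cat] = counts[ogs].sum(axis=1) if ogs else 0
    return pd.DataFrame(data, index=counts.index)


def bray_curtis(profiles: pd.DataFrame) -> PairwiseMatrix:
    """Bray–Curtis dissimilarity between genome profiles.

    BC(x, y) = sum|x_i − y_i| / sum(x_i + y_i); a pair of all-zero profiles is
    reported as distance 0 with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genomes")
    x = profiles.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(vals).any():
        import warnings

        warnings.warn("all-zero profile pair: Bray-Curtis distance set to 0")
        vals = np.nan_to_num(vals, nan=0.0)
    return PairwiseMatrix(list(profiles.index), vals, "BRAYCURTIS")


def pcoa(D: PairwiseMatrix) -> Ordination:
    """Classical multidimensional scaling of a distance matrix.

    Negative eigenvalues (from non-Euclidean input) are dropped and counted.
    """
    vals = (D.values + D.values.T) / 2.0
    assert np.allclose(np.diag(vals), 0.0), "nonzero diagonal"
    from skbio import DistanceMatrix

    res = _skbio_pcoa(DistanceMatrix(vals, D.genome_ids), method="eigh")
    eig = res.eigvals.to_numpy()
    keep = eig > 1e-12
    n_negative = int((eig < -1e-12).sum())
    coords = res.samples.to_numpy()[:, keep]
    return Ordination(
        coordinates=pd.DataFrame(
            coords,
            index=D.genome_ids,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eig[keep],
        proportion_explained=res.proportion_explained.to_numpy()[keep],
        n_negative_dropped=n_negative,
    )
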