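"""Shared fixtures.

The expensive study-scale dataset (three clades of 10 genomes at 300 kb,
seed 42) and its full pipeline run are session-scoped so the end-to-end
checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from caseikit.pipeline import PipelineConfig, input_from_dataset, run_pipeline
from caseikit.simulate import SimConfig, simulate_group


@pytest.fixture(scope="session")
def small_dataset():
    """A light clade-structured dataset for unit-level checks."""
    cfg = SimConfig(
        seed=7,
        n_per_clade={"A": 2, "B": 4, "C": 2},
        genome_length=100_000,
        n_core_genes=30,
        n_accessory_genes=12,
    )
    return simulate_group(cfg)


@pytest.fixture(scope="session")
def study_dataset():
    """The study-scale synthetic dataset: 10 genomes per clade at 300 kb."""
    return simulate_group(SimConfig(seed=42))


@pytest.fixture(scope="session")
def study_report(study_dataset):
    """Full pipeline run over the study-scale dataset."""
    return run_pipeline(
        input_from_dataset(study_dataset),
        PipelineConfig(bootstrap_reps=100, bootstrap_seed=42),
        log=lambda *a: None,
    )


def random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute exactly round(rate * len) positions to a different base."""
    out = list(seq)
    n = round(rate * len(seq))
    for p in rng.choice(len(seq), size=n, replace=False):
        out[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(out)
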