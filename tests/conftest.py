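"""Shared fixtures: deterministic random sequences and small synthetic genomes."""

from __future__ import annotations

import numpy as np
import pytest

from phagecode.seq_core import GenomeRecord
from phagecode.synthetic_data import SyntheticSpec, generate_genome


def random_dna(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), length))


def substitute(seq: str, rate: float, seed: int) -> tuple[str, int]:
    """Substitution-only mutant and the realized substitution count."""
    rng = np.random.default_rng(seed)
    out = list(seq)
    n = 0
    for p in range(len(seq)):
        if rng.random() < rate:
            out[p] = "ACGT".replace(seq[p], "")[int(rng.integers(0, 3))]
            n += 1
    return "".join(out), n


@pytest.fixture
def random_genome() -> GenomeRecord:
    return GenomeRecord(id="rand", seq=random_dna(5000, 42))


@pytest.fixture
def small_recoded():
    """A 40-gene genome with 12 recoded genes and one suppressor tRNA."""
    spec = SyntheticSpec(
        n_genes=40, gene_length_aa=(150, 300), recoded_fraction=0.3,
        ambers_per_recoded_gene=(2, 4), n_suppressor_trnas=1, seed=2,
    )
    return generate_genome(spec)


@pytest.fixture
def small_standard():
    spec = SyntheticSpec(
        n_genes=20, gene_length_aa=(150, 300), recoded_fraction=0.0,
        n_suppressor_trnas=0, seed=3,
    )
    return generate_genome(spec)
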