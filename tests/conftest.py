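"""Shared fixtures and dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from urbanbarrier.genotype_io import LocusDef, MicrosatDataset, SampleRecord
from urbanbarrier.synthetic_city import SimulationConfig


def make_dataset(
    genotypes,
    xs=None,
    ys=None,
    blocks=None,
    years=None,
    loci=None,
    ids=None,
) -> MicrosatDataset:
    """Assemble a small dataset from per-sample genotype lists.

    ``genotypes`` is a list (samples) of lists (loci) of (a1, a2) tuples or
    None.  Metadata defaults: samples on a line 100 m apart, one block,
    one year.
    """
    n = len(genotypes)
    n_loci = len(genotypes[0])
    xs = xs if xs is not None else [100.0 * i for i in range(n)]
    ys = ys if ys is not None else [0.0] * n
    blocks = blocks if blocks is not None else ["b1"] * n
    years = years if years is not None else [2008] * n
    ids = ids if ids is not None else [f"s{i + 1}" for i in range(n)]
    loci = loci if loci is not None else tuple(LocusDef(f"L{k + 1}") for k in range(n_loci))
    samples = tuple(
        SampleRecord(
            sample_id=ids[i], x=xs[i], y=ys[i], block_id=blocks[i],
            year=years[i], genotype=tuple(genotypes[i]),
        )
        for i in range(n)
    )
    return MicrosatDataset(loci=tuple(loci), samples=samples)


def random_genotype(rng: np.random.Generator, n_loci: int, missing_p: float = 0.0):
    """One multilocus genotype with alleles on a 2 bp grid from 100."""
    geno = []
    for _ in range(n_loci):
        if missing_p and rng.random() < missing_p:
            geno.append(None)
            continue
        a, b = 100 + 2 * rng.integers(0, 8, size=2)
        geno.append((min(a, b), max(a, b)))
    return tuple(geno)


def random_dataset(
    rng: np.random.Generator,
    n_samples: int = 12,
    n_loci: int = 4,
    n_blocks: int = 3,
    years=(2008, 2011),
    missing_p: float = 0.0,
) -> MicrosatDataset:
    genos = [random_genotype(rng, n_loci, missing_p) for _ in range(n_samples)]
    return make_dataset(
        genos,
        xs=list(rng.uniform(0, 1000, n_samples)),
        ys=list(rng.uniform(0, 300, n_samples)),
        blocks=[f"b{rng.integers(n_blocks)}" for _ in range(n_samples)],
        years=[int(years[i % len(years)]) for i in range(n_samples)],
    )


def small_sim_config(p_street: float, p_jump: float, seed: int) -> SimulationConfig:
    """The scaled replicate condition for calibration studies: a 6x2 block
    grid, 5 loci, 60 samples over two collection years."""
    return SimulationConfig(
        n_cols=6, n_rows=2, block_side=80, street_width=10,
        n_per_block=30, n_loci=5, p_street=p_street, p_jump=p_jump,
        founding_interval=4, n_generations=32, sample_years=(29, 32),
        samples_per_year=30, seed=seed,
    )


@pytest.fixture(scope="session")
def default_sim_dataset():
    """One default-conditions simulated dataset, shared across tests."""
    from urbanbarrier.synthetic_city import default_study_config, simulate

    return simulate(default_study_config(seed=11))
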