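"""Neighborhood diversity indices, rarefaction, radius rule, trends."""

import itertools
import math

import numpy as np
import pytest

from urbanbarrier.neighborhood import (
    levels_off_selection,
    longitudinal_trend,
    neighborhood_indices,
    select_radius,
)
from .conftest import make_dataset


def cluster_dataset(genotypes, center=(0.0, 0.0)):
    """All samples within 1 m of each other: one shared neighborhood."""
    n = len(genotypes)
    return make_dataset(
        genotypes,
        xs=[center[0] + 0.1 * i for i in range(n)],
        ys=[center[1]] * n,
    )


def test_two_individual_worked_example():
    """Genotypes (A,A) and (A,B): Ho = 0.5, unbiased He = 0.5, F_IS = 0."""
    ds = cluster_dataset([[(100, 100)], [(100, 102)]])
    idx = neighborhood_indices(ds, radius=10, min_n=2, rarefaction_g=2)
    assert all(i.valid for i in idx)
    i = idx[0]
    assert i.ho == pytest.approx(0.5)
    assert i.he == pytest.approx(0.5)  # (4/3) * (1 - (0.75^2 + 0.25^2))
    assert i.f_is == pytest.approx(0.0)


def test_rarefied_richness_hypergeometric_example():
    """Allele counts 3 and 1 of 4 copies, rarefied to g' = 2:
    AR = [1 - 0] + [1 - C(3,2)/C(4,2)] = 1.5."""
    ds = cluster_dataset([[(100, 100)], [(100, 102)]])
    idx = neighborhood_indices(ds, radius=10, min_n=2, rarefaction_g=1)
    assert idx[0].ar == pytest.approx(1.5)


def test_monomorphic_limit():
    ds = cluster_dataset([[(100, 100)] for _ in range(5)])
    with pytest.warns(UserWarning, match="monomorphic"):
        idx = neighborhood_indices(ds, radius=10, min_n=2, rarefaction_g=2)
    i = idx[0]
    assert i.ho == 0.0 and i.he == 0.0
    assert i.f_is is None
    assert i.ar == pytest.approx(1.0)


def test_rarefaction_matches_exhaustive_enumeration():
    """AR equals the mean distinct-allele count over all subsets of g'
    gene copies, enumerated exhaustively for 2n <= 8."""
    rng = np.random.default_rng(8)
    for _ in range(20):
        n_ind = int(rng.integers(2, 5))  # 2n in 4..8
        genos = [
            [tuple(sorted(100 + 2 * rng.integers(0, 4, size=2)))]
            for _ in range(n_ind)
        ]
        copies = [a for g in genos for a in g[0]]
        for g_sub in range(1, n_ind + 1):
            g_prime = 2 * g_sub
            expect = np.mean(
                [
                    len({copies[i] for i in sub})
                    for sub in itertools.combinations(range(len(copies)), g_prime)
                ]
            )
            ds = cluster_dataset(genos)
            idx = neighborhood_indices(ds, radius=10, min_n=2, rarefaction_g=g_sub)
            assert idx[0].ar == pytest.approx(expect, abs=1e-12)


def test_rarefied_ar_monotone_in_subsample_size():
    genos = [[(100, 102)], [(104, 104)], [(100, 106)], [(102, 104)]]
    ds = cluster_dataset(genos)
    ars = [
        neighborhood_indices(ds, radius=10, min_n=2, rarefaction_g=g)[0].ar
        for g in (1, 2, 3, 4)
    ]
    assert all(a <= b + 1e-12 for a, b in zip(ars, ars[1:]))
    # at g' = 2n the rarefied value equals the observed distinct count
    assert ars[-1] == pytest.approx(4.0)


def test_fis_near_zero_under_random_mating():
    """Mean neighborhood F_IS over HW-sampled neighborhoods is ~0."""
    rng = np.random.default_rng(9)
    fis_vals = []
    for _ in range(200):
        freqs = rng.dirichlet(np.ones(4))
        alleles = 100 + 2 * np.arange(4)
        genos = [
            [tuple(sorted(rng.choice(alleles, size=2, p=freqs)))]
            for _ in range(30)
        ]
        ds = cluster_dataset(genos)
        idx = neighborhood_indices(ds, radius=20, min_n=2, rarefaction_g=2)
        if idx[0].f_is is not None:
            fis_vals.append(idx[0].f_is)
    assert abs(np.mean(fis_vals)) < 0.05


def test_self_inclusion_and_min_n_exclusion():
    ds = make_dataset(
        [[(100, 102)], [(100, 100)], [(102, 102)]],
        xs=[0.0, 5.0, 1000.0],
        ys=[0.0, 0.0, 0.0],
    )
    idx = neighborhood_indices(ds, radius=10, min_n=2, rarefaction_g=2)
    assert idx[0].n_neighbors == 2  # focal counts itself plus one neighbor
    assert idx[2].n_neighbors == 1  # isolated: itself only
    assert not idx[2].valid and idx[2].ho is None


def test_invalid_arguments():
    ds = cluster_dataset([[(100, 102)], [(100, 100)]])
    with pytest.raises(ValueError):
        neighborhood_indices(ds, radius=0)
    with pytest.raises(ValueError):
        neighborhood_indices(ds, radius=10, min_n=1)


# ---------------------------------------------------------------------------
# radius rule
# ---------------------------------------------------------------------------

def test_levels_off_rule_on_constructed_counts():
    radii = [100, 125, 150, 175, 200, 225, 250]
    counts = [30, 60, 100, 140, 160, 165, 166]
    # first relative increase below 5% is 165 vs 160 (+3.1%) at 225 m
    assert levels_off_selection(radii, counts, 0.05) == 225
    # strictly linear growth: +20 each step keeps the relative gain above
    # 5% throughout, so the rule never fires
    lin = [20 * (k + 1) for k in range(7)]
    assert levels_off_selection(radii, lin, 0.05) is None
    # but a long shallow series does fire once the base is large enough
    shallow = [100, 160, 200, 206, 210]
    assert levels_off_selection([50, 100, 150, 200, 250], shallow, 0.05) == 200
    # constant counts: immediate plateau selects the second radius
    assert levels_off_selection(radii, [50] * 7, 0.05) == 125
    # never levels off
    assert levels_off_selection([1, 2, 3], [10, 20, 40], 0.05) is None


def test_select_radius_counts_monotone(default_sim_dataset):
    scan = select_radius(default_sim_dataset, radii=(50, 100, 150, 200, 250), min_n=10)
    assert scan.valid_counts == sorted(scan.valid_counts)
    assert scan.selected in scan.radii


def test_select_radius_validation():
    ds = cluster_dataset([[(100, 102)], [(100, 100)]])
    with pytest.raises(ValueError):
        select_radius(ds, radii=(100,))
    with pytest.raises(ValueError):
        select_radius(ds, radii=(200, 100))


# ---------------------------------------------------------------------------
# longitudinal trend
# ---------------------------------------------------------------------------

def test_trend_recovers_exact_linear_signal():
    n = 30
    xs = np.linspace(0, 1000, n)
    genos = [[(100, 102)] for _ in range(n)]
    ds = make_dataset(genos, xs=list(xs), ys=[0.0] * n)
    from urbanbarrier.neighborhood import NeighborhoodIndex

    indices = [
        NeighborhoodIndex(f"s{i + 1}", 10, float(0.5 - 3e-4 * xs[i]), 0.5, 0.0, 2.0, True)
        for i in range(n)
    ]
    fit = longitudinal_trend(indices, ds, "ho")
    assert fit.slope == pytest.approx(-3e-4, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.n == n


def test_trend_null_r_squared_small():
    rng = np.random.default_rng(10)
    n = 120
    xs = np.linspace(0, 1000, n)
    ds = make_dataset([[(100, 102)] for _ in range(n)], xs=list(xs), ys=[0.0] * n)
    from urbanbarrier.neighborhood import NeighborhoodIndex

    r2 = []
    for _ in range(30):
        vals = rng.uniform(0, 1, n)
        indices = [
            NeighborhoodIndex(f"s{i + 1}", 10, float(vals[i]), 0.5, 0.0, 2.0, True)
            for i in range(n)
        ]
        r2.append(longitudinal_trend(indices, ds, "ho").r_squared)
    assert np.median(r2) < 0.05


def test_trend_errors():
    ds = cluster_dataset([[(100, 102)], [(100, 100)]])
    with pytest.raises(ValueError):
        longitudinal_trend([], ds, "ho")
    with pytest.raises(ValueError):
        longitudinal_trend([], ds, "bogus")
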