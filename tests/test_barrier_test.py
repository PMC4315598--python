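"""Permutation regression and matched equal-distance pair analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from urbanbarrier.barrier_test import (
    DegenerateDesignError,
    fit_distance_regression,
    match_equidistant_pairs,
    paired_t_test,
    permutation_test,
    year_stratified_permutation,
)
from urbanbarrier.pairwise import PairTable, build_pair_table
from .conftest import make_dataset, random_dataset, small_sim_config
from urbanbarrier.synthetic_city import simulate


def pair_df(euclid, cross_year, cross_block, genetic_d):
    n = len(euclid)
    return pd.DataFrame(
        {
            "id_i": [f"a{k}" for k in range(n)],
            "id_j": [f"b{k}" for k in range(n)],
            "genetic_d": genetic_d,
            "euclid_m": euclid,
            "cross_year": cross_year,
            "cross_block": cross_block,
            "n_loci_used": [5] * n,
        }
    )


# ---------------------------------------------------------------------------
# OLS fit
# ---------------------------------------------------------------------------

def test_noiseless_coefficients_recovered_exactly():
    rng = np.random.default_rng(1)
    n = 40
    euclid = rng.uniform(0, 500, n)
    block = rng.integers(0, 2, n)
    y = 0.1 + 2e-5 * euclid + 0.07 * block
    df = pair_df(euclid, np.zeros(n, dtype=int), block, y)
    fit = fit_distance_regression(df)
    assert fit.beta0 == pytest.approx(0.1, abs=1e-12)
    assert fit.beta_dist == pytest.approx(2e-5, abs=1e-12)
    assert fit.beta_block == pytest.approx(0.07, abs=1e-12)
    assert np.isnan(fit.beta_year)  # constant predictor dropped
    assert fit.r_squared == pytest.approx(1.0)


def test_six_pair_normal_equations_oracle():
    euclid = np.array([10.0, 50.0, 90.0, 130.0, 170.0, 210.0])
    year = np.array([0, 1, 0, 1, 0, 1])
    block = np.array([0, 0, 1, 1, 0, 1])
    y = np.array([0.12, 0.35, 0.28, 0.44, 0.2, 0.5])
    df = pair_df(euclid, year, block, y)
    fit = fit_distance_regression(df)
    X = np.column_stack([np.ones(6), euclid, year, block])
    beta_hat = np.linalg.solve(X.T @ X, X.T @ y)  # hand normal equations
    assert fit.beta0 == pytest.approx(beta_hat[0], abs=1e-10)
    assert fit.beta_dist == pytest.approx(beta_hat[1], abs=1e-10)
    assert fit.beta_year == pytest.approx(beta_hat[2], abs=1e-10)
    assert fit.beta_block == pytest.approx(beta_hat[3], abs=1e-10)


def test_independent_response_gives_near_zero_r_squared():
    rng = np.random.default_rng(2)
    n = 2000
    df = pair_df(
        rng.uniform(0, 500, n),
        rng.integers(0, 2, n),
        rng.integers(0, 2, n),
        rng.uniform(0, 1, n),
    )
    fit = fit_distance_regression(df)
    assert fit.r_squared < 0.05


def test_all_constant_design_raises():
    n = 10
    df = pair_df(np.full(n, 5.0), np.zeros(n, int), np.ones(n, int), np.linspace(0, 1, n))
    with pytest.raises(DegenerateDesignError):
        fit_distance_regression(df)


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def test_stratified_permutation_preserves_year_multisets():
    rng = np.random.default_rng(0)
    years = np.array([2008] * 7 + [2011] * 5 + [2008] * 3)
    for _ in range(50):
        p = year_stratified_permutation(years, rng)
        assert sorted(p) == list(range(len(years)))
        # every index stays inside its own year stratum
        assert (years[p] == years).all()


def test_identical_genotypes_give_unit_p_values():
    geno = [(100, 102), (200, 200)]
    ds = make_dataset(
        [list(geno) for _ in range(8)],
        xs=list(np.linspace(0, 700, 8)),
        blocks=["b1", "b2"] * 4,
        years=[2008] * 4 + [2011] * 4,
    )
    res = permutation_test(ds, n_perm=99, seed=1)
    assert res.observed.beta_block == pytest.approx(0.0)
    assert np.allclose(res.null_betas, 0.0)
    assert all(p == 1.0 for p in res.p_values.values())


def test_p_value_bounds_and_reproducibility():
    rng = np.random.default_rng(3)
    ds = random_dataset(rng, n_samples=16, n_loci=4)
    r1 = permutation_test(ds, n_perm=99, seed=7)
    r2 = permutation_test(ds, n_perm=99, seed=7)
    assert r1.p_values == r2.p_values
    assert np.array_equal(r1.null_betas, r2.null_betas)
    lo = 1 / (99 + 1)
    for p in r1.p_values.values():
        assert lo <= p <= 1.0
    r3 = permutation_test(ds, n_perm=99, seed=8)
    assert not np.array_equal(r1.null_betas, r3.null_betas)


def test_permutation_rejects_simulated_barrier():
    ds = simulate(small_sim_config(p_street=0.002, p_jump=0.0005, seed=21))
    res = permutation_test(ds, n_perm=199, seed=22)
    assert res.observed.beta_block > 0
    assert res.p_values["beta_block"] <= 0.05


def test_block_p_values_uniform_under_exchangeable_null():
    """Kolmogorov-Smirnov check of p-value uniformity on label-exchangeable
    data: genotypes drawn i.i.d., independent of location.  (Drift-heavy
    datasets with few distinct genotypes give ties and hence slightly
    conservative p-values; exact uniformity holds in the tie-free case.)"""
    pvals = []
    for rep in range(200):
        rng = np.random.default_rng(7000 + rep)
        ds = random_dataset(rng, n_samples=40, n_loci=6, n_blocks=5)
        res = permutation_test(ds, n_perm=99, seed=9000 + rep)
        pvals.append(res.p_values["beta_block"])
    stat, ks_p = sps.kstest(pvals, "uniform")
    assert ks_p > 0.01


def test_n_perm_validation():
    rng = np.random.default_rng(5)
    ds = random_dataset(rng, n_samples=8, n_loci=3)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_test(ds, n_perm=0, seed=1)


# ---------------------------------------------------------------------------
# matched pairs
# ---------------------------------------------------------------------------

def matched_table(same_d, cross_d):
    """Pair table with given same-block and cross-block distances."""
    rows = []
    for k, d in enumerate(same_d):
        rows.append(("s", k, d))
    for k, d in enumerate(cross_d):
        rows.append(("c", k, d))
    return pd.DataFrame(
        {
            "id_i": [f"{t}{k}_i" for t, k, _ in rows],
            "id_j": [f"{t}{k}_j" for t, k, _ in rows],
            "genetic_d": [0.2 if t == "s" else 0.4 for t, _, _ in rows],
            "euclid_m": [d for _, _, d in rows],
            "cross_block": [0 if t == "s" else 1 for t, _, _ in rows],
            "cross_year": 0,
            "n_loci_used": 5,
        }
    )


def test_greedy_matching_picks_nearest_within_tolerance():
    df = matched_table([120.4], [119.8, 135.0])
    m = match_equidistant_pairs(PairTable(df=df), tolerance=1.0)
    assert len(m) == 1
    assert m.df.iloc[0]["cross_euclid_m"] == pytest.approx(119.8)
    assert m.df.iloc[0]["delta_m"] == pytest.approx(0.6)


def test_matching_respects_tolerance():
    df = matched_table([100.0], [102.3])
    with pytest.raises(ValueError, match="tolerance"):
        match_equidistant_pairs(PairTable(df=df), tolerance=1.0)


def test_each_cross_pair_used_once_and_deterministic():
    df = matched_table([100.0, 100.2, 300.0], [100.1, 100.3, 299.5, 420.0])
    m1 = match_equidistant_pairs(PairTable(df=df), tolerance=1.0)
    m2 = match_equidistant_pairs(PairTable(df=df), tolerance=1.0)
    pd.testing.assert_frame_equal(m1.df, m2.df)
    used = list(m1.df["cross_id_i"])
    assert len(used) == len(set(used))
    assert len(m1) == 3
    assert (m1.df["delta_m"] <= 1.0).all()


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

def couples_from_differences(diffs):
    n = len(diffs)
    return pd.DataFrame(
        {
            "same_id_i": [f"s{k}" for k in range(n)],
            "same_id_j": [f"t{k}" for k in range(n)],
            "same_euclid_m": 100.0,
            "same_genetic_d": 0.3,
            "cross_id_i": [f"u{k}" for k in range(n)],
            "cross_id_j": [f"v{k}" for k in range(n)],
            "cross_euclid_m": 100.0,
            "cross_genetic_d": [0.3 + d for d in diffs],
            "delta_m": 0.0,
        }
    )


def test_paired_t_null_identity():
    from urbanbarrier.barrier_test import MatchedPairSet

    m = MatchedPairSet(df=couples_from_differences([0.0, 0.0, 0.0]), tolerance=1.0)
    res = paired_t_test(m)
    assert res.t_stat == 0.0 and res.p_two_sided == 1.0


def test_paired_t_hand_formula():
    from urbanbarrier.barrier_test import MatchedPairSet

    m = MatchedPairSet(df=couples_from_differences([0.1, 0.2, 0.3]), tolerance=1.0)
    res = paired_t_test(m)
    assert res.t_stat == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-4)
    assert res.t_stat == pytest.approx(3.4641, abs=1e-4)
    assert res.df == 2


def test_paired_t_matches_scipy_oracle():
    from urbanbarrier.barrier_test import MatchedPairSet

    rng = np.random.default_rng(6)
    diffs = rng.normal(0.05, 0.1, 30)
    m = MatchedPairSet(df=couples_from_differences(diffs), tolerance=1.0)
    res = paired_t_test(m)
    ref = sps.ttest_rel(0.3 + diffs, np.full(30, 0.3))
    assert res.t_stat == pytest.approx(ref.statistic)
    assert res.p_two_sided == pytest.approx(ref.pvalue)
    assert res.df == 29
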