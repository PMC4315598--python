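"""Street-barrier inference: permutation regression and matched-pair test.

The core analysis regresses pairwise genetic dissimilarity on pairwise
Euclidean distance and the cross-year / cross-block indicators by ordinary
least squares, but draws inference only from a year-stratified permutation
null: whole multilocus genotypes are shuffled among individuals collected
in the same year (spatial metadata fixed), the genetic distances are
rebuilt, and the regression refit.  The p-value of each predictor is the
add-one two-sided tail probability of the observed coefficient within its
null distribution.  OLS standard errors are never used for inference —
pairs of a distance table are not independent observations.

A complementary design controls for distance exactly: same-block pairs are
greedily matched to unused cross-block pairs of (nearly) equal Euclidean
distance, and the genetic-distance differences across the matched couples
are tested with a paired t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype_io import MicrosatDataset
from .pairwise import PairTable, build_pair_table, genetic_distance_matrix

__all__ = [
    "RegressionFit",
    "PermutationResult",
    "MatchedPairSet",
    "PairedTestResult",
    "DegenerateDesignError",
    "fit_distance_regression",
    "permutation_test",
    "year_stratified_permutation",
    "match_equidistant_pairs",
    "paired_t_test",
]

logger = logging.getLogger(__name__)

_PREDICTORS = ["euclid_m", "cross_year", "cross_block"]
_BETA_NAMES = ["beta_dist", "beta_year", "beta_block"]


class DegenerateDesignError(ValueError):
    """The regression design is rank deficient; the message names the
    degenerate predictor(s)."""


@dataclass
class RegressionFit:
    """OLS fit of genetic_d ~ euclid_m + cross_year + cross_block.

    Coefficients for predictors that are constant in the data (and were
    therefore dropped from the design) are NaN.
    """

    beta0: float
    beta_dist: float
    beta_year: float
    beta_block: float
    r_squared: float
    f_stat: float
    n_pairs: int

    def betas(self) -> np.ndarray:
        return np.array([self.beta_dist, self.beta_year, self.beta_block])


def _design(df: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix with intercept; constant predictors are dropped.

    Returns (X, kept predictor names, dropped predictor names).
    """
    kept, dropped = [], []
    cols = []
    for name in _PREDICTORS:
        v = df[name].to_numpy(dtype=float)
        if np.ptp(v) == 0.0:
            dropped.append(name)
        else:
            kept.append(name)
            cols.append(v)
    if not kept:
        raise DegenerateDesignError(
            "all predictors are constant: " + ", ".join(_PREDICTORS)
        )
    X = np.column_stack([np.ones(len(df))] + cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the collinear predictor(s): those whose removal restores rank
        bad = []
        for k, name in enumerate(kept):
            Xk = np.delete(X, k + 1, axis=1)
            if np.linalg.matrix_rank(Xk) == Xk.shape[1]:
                bad.append(name)
        raise DegenerateDesignError(
            f"rank-deficient design; degenerate predictor(s): {bad or kept}"
        )
    return X, kept, dropped


def fit_distance_regression(pairs: PairTable | pd.DataFrame) -> RegressionFit:
    """OLS of genetic distance on distance / cross-year / cross-block.

    Point estimates and fit statistics only; see :func:`permutation_test`
    for inference.
    """
    df = pairs.df if isinstance(pairs, PairTable) else pairs
    if len(df) < 4:
        raise ValueError(f"need at least 4 pairs to fit, got {len(df)}")
    X, kept, dropped = _design(df)
    if dropped:
        logger.warning("constant predictor(s) dropped from design: %s", dropped)
    y = df["genetic_d"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    coef = dict(zip(kept, res.params[1:]))
    return RegressionFit(
        beta0=float(res.params[0]),
        beta_dist=float(coef.get("euclid_m", np.nan)),
        beta_year=float(coef.get("cross_year", np.nan)),
        beta_block=float(coef.get("cross_block", np.nan)),
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        n_pairs=len(df),
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def year_stratified_permutation(
    years: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """A permutation of 0..n-1 that only moves indices within year strata."""
    years = np.asarray(years)
    p = np.arange(len(years))
    for y in np.unique(years):
        idx = np.flatnonzero(years == y)
        p[idx] = idx[rng.permutation(len(idx))]
    return p


@dataclass
class PermutationResult:
    """Observed fit, permutation null, and per-predictor p-values.

    ``null_betas`` has one row per permutation and columns (dist, year,
    block); ``p_values`` maps ``beta_dist``/``beta_year``/``beta_block`` to
    add-one two-sided permutation p-values (NaN for dropped predictors).
    """

    observed: RegressionFit
    null_betas: np.ndarray
    p_values: dict[str, float]
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        obs = self.observed
        return {
            "observed": {
                "beta0": obs.beta0,
                "beta_dist": obs.beta_dist,
                "beta_year": obs.beta_year,
                "beta_block": obs.beta_block,
                "r_squared": obs.r_squared,
                "f_stat": obs.f_stat,
                "n_pairs": obs.n_pairs,
            },
            "p_values": self.p_values,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def permutation_test(
    ds: MicrosatDataset,
    n_perm: int = 10_000,
    seed: int = 0,
    within_year: bool = False,
) -> PermutationResult:
    """Year-stratified permutation test of the distance regression.

    Whole multilocus genotypes are shuffled among samples of the same
    collection year; Euclidean distances and the indicator columns are
    untouched, so each permutation only rewrites the genetic-distance
    column (a row/column relabeling of the precomputed dissimilarity
    matrix).  Reproducible for a fixed ``seed``.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    pt = build_pair_table(ds, within_year=within_year)
    observed = fit_distance_regression(pt)
    years = np.array([s.year for s in ds.samples])
    for y, cnt in zip(*np.unique(years, return_counts=True)):
        if cnt < 2:
            warnings.warn(
                f"year stratum {y} has a single sample; it is a fixed point "
                "of every permutation"
            )
    D, shared = genetic_distance_matrix(ds)
    n = ds.n_samples
    ii, jj = np.triu_indices(n, k=1)
    if within_year:
        keep = years[ii] == years[jj]
        ii, jj = ii[keep], jj[keep]
    # design over *all* candidate pairs; per-permutation masks drop pairs
    # that share no typed locus under that genotype relabeling
    ids = np.array(ds.sample_ids)
    blocks = np.array([s.block_id for s in ds.samples])
    xy = np.array([[s.x, s.y] for s in ds.samples])
    euclid = np.sqrt(((xy[ii] - xy[jj]) ** 2).sum(axis=1))
    full = pd.DataFrame(
        {
            "euclid_m": euclid,
            "cross_year": (years[ii] != years[jj]).astype(int),
            "cross_block": (blocks[ii] != blocks[jj]).astype(int),
        }
    )
    full["genetic_d"] = 0.0  # placeholder; _design ignores the response
    X, kept, _ = _design(full)
    kept_idx = {name: k for k, name in enumerate(kept)}
    no_missing = not np.isnan(D[ii, jj]).any() and (shared[ii, jj] >= 1).all()
    pinv = np.linalg.pinv(X) if no_missing else None

    rng = np.random.default_rng(seed)
    null = np.full((n_perm, 3), np.nan)
    for t in range(n_perm):
        p = year_stratified_permutation(years, rng)
        y_perm = D[p[ii], p[jj]]
        if no_missing:
            beta = pinv @ y_perm
        else:
            mask = np.isfinite(y_perm)
            beta, *_ = np.linalg.lstsq(X[mask], y_perm[mask], rcond=None)
        for name, col in zip(_PREDICTORS, range(3)):
            if name in kept_idx:
                null[t, col] = beta[1 + kept_idx[name]]
    obs_betas = observed.betas()
    p_values: dict[str, float] = {}
    for col, (pred, beta_name) in enumerate(zip(_PREDICTORS, _BETA_NAMES)):
        if pred not in kept_idx:
            p_values[beta_name] = float("nan")
            continue
        exceed = np.sum(np.abs(null[:, col]) >= abs(obs_betas[col]))
        p_values[beta_name] = float((1 + exceed) / (n_perm + 1))
    return PermutationResult(
        observed=observed, null_betas=null, p_values=p_values,
        n_perm=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# matched equal-distance pairs
# ---------------------------------------------------------------------------

@dataclass
class MatchedPairSet:
    """Couples of (same-block pair, cross-block pair) matched on distance.

    ``df`` has one row per couple with the two pairs' ids, genetic and
    Euclidean distances, and ``delta_m`` = |distance difference| (always
    <= ``tolerance``).  Each underlying pair is used at most once.
    """

    df: pd.DataFrame
    tolerance: float

    def __len__(self) -> int:
        return len(self.df)

    def differences(self) -> np.ndarray:
        """Genetic-distance differences, cross-block minus same-block."""
        return (self.df["cross_genetic_d"] - self.df["same_genetic_d"]).to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def match_equidistant_pairs(
    pairs: PairTable | pd.DataFrame, tolerance: float = 1.0
) -> MatchedPairSet:
    """Greedily match same-block pairs to cross-block pairs of equal
    Euclidean distance (within ``tolerance`` meters).

    Same-block pairs are visited in order of increasing distance; each
    takes the unused cross-block pair minimizing the distance difference,
    accepted only when that difference is within tolerance.  Deterministic
    for a given table.
    """
    df = pairs.df if isinstance(pairs, PairTable) else pairs
    same = df[df["cross_block"] == 0]
    cross = df[df["cross_block"] == 1]
    if len(same) == 0 or len(cross) == 0:
        raise ValueError("table needs both same-block and cross-block pairs")
    same = same.sort_values("euclid_m", kind="stable")
    cross = cross.sort_values("euclid_m", kind="stable").reset_index(drop=True)
    cdist = cross["euclid_m"].to_numpy()
    used = np.zeros(len(cross), dtype=bool)
    rows = []
    for _, srow in same.iterrows():
        d = srow["euclid_m"]
        k = int(np.searchsorted(cdist, d))
        # candidates are sorted by distance, so the nearest unused above and
        # below the insertion point bracket the global nearest unused
        hi = k
        while hi < len(cdist) and used[hi]:
            hi += 1
        lo = k - 1
        while lo >= 0 and used[lo]:
            lo -= 1
        cands = []
        if hi < len(cdist):
            cands.append((float(cdist[hi] - d), hi))
        if lo >= 0:
            cands.append((float(d - cdist[lo]), lo))
        if not cands:
            continue
        best_delta, best = min(cands)
        if best_delta > tolerance:
            continue
        used[best] = True
        crow = cross.iloc[best]
        rows.append(
            {
                "same_id_i": srow["id_i"],
                "same_id_j": srow["id_j"],
                "same_euclid_m": srow["euclid_m"],
                "same_genetic_d": srow["genetic_d"],
                "cross_id_i": crow["id_i"],
                "cross_id_j": crow["id_j"],
                "cross_euclid_m": crow["euclid_m"],
                "cross_genetic_d": crow["genetic_d"],
                "delta_m": best_delta,
            }
        )
    if not rows:
        raise ValueError(
            f"no equal-distance couples found within tolerance {tolerance} m"
        )
    return MatchedPairSet(df=pd.DataFrame(rows), tolerance=tolerance)


@dataclass
class PairedTestResult:
    """Two-sided paired t-test on matched-couple genetic distances."""

    t_stat: float
    df: int
    p_two_sided: float
    mean_difference: float
    n_couples: int


def paired_t_test(m: MatchedPairSet) -> PairedTestResult:
    """Paired t-test of cross-block minus same-block genetic distance."""
    d = m.differences()
    n = len(d)
    if n < 2:
        raise ValueError(f"need at least 2 couples, got {n}")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, n - 1, 1.0, 0.0, n)
        warnings.warn("zero variance of differences with nonzero mean; p -> 0")
        return PairedTestResult(
            float(np.inf) if mean > 0 else float(-np.inf), n - 1, 0.0, mean, n
        )
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(float(t), n - 1, float(p), mean, n)
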