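"""Post-processing of external clustering runs.

The Bayesian clustering itself (admixture-model MCMC) is out of scope;
this module consumes its outputs: per-run log-likelihoods across candidate
cluster numbers K (for the Evanno delta-K selection), and Q-matrices of
per-individual membership probabilities (for hard modal assignments and
the same-block co-assignment test).

Evanno's delta-K at an interior K is |L''(K)| / sd(lnP(K)) where
L'(K) = mean lnP(K) - mean lnP(K-1), L''(K) = L'(K+1) - L'(K), and the
standard deviation is across independent runs at that K; the K maximizing
delta-K is selected.

The co-assignment test asks whether samples from the same city block land
in the same cluster more often than chance: the observed proportion of
co-assigned same-block pairs is compared to sum_k q_k^2 (the chance two
random samples share a label under the observed label frequencies) with a
1-df goodness-of-fit chi-square on the co-assigned / not-co-assigned
split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MicrosatDataset, MissingMetadataError

__all__ = [
    "DeltaKTable",
    "CoassignmentResult",
    "delta_k",
    "modal_assignment",
    "coassignment_test",
    "coassignment_chi_square",
    "read_run_likelihoods",
    "read_qmatrix",
]


def read_run_likelihoods(path) -> pd.DataFrame:
    """Read a run-likelihood CSV with columns K, run, lnP."""
    df = pd.read_csv(path)
    missing = {"K", "run", "lnP"} - set(df.columns)
    if missing:
        raise ValueError(f"run-likelihood table lacks columns {sorted(missing)}")
    return df


@dataclass
class DeltaKTable:
    """Evanno bookkeeping per interior K plus the selected K.

    ``table`` columns: K, mean_lnP, sd_lnP, lprime, lsecond, delta_k
    (NaN where undefined: the boundary K values, and any K whose across-run
    sd is zero).
    """

    table: pd.DataFrame
    selected_k: Optional[int]


def delta_k(runs: pd.DataFrame) -> DeltaKTable:
    """Evanno delta-K statistics from per-run log-likelihoods.

    ``runs`` needs columns ``K``, ``run``, ``lnP`` with >= 2 runs at each
    of >= 3 contiguous K values.
    """
    if isinstance(runs, (list, tuple)):
        runs = pd.DataFrame(runs, columns=["K", "run", "lnP"])
    for col in ("K", "lnP"):
        if col not in runs.columns:
            raise ValueError(f"runs table lacks column {col!r}")
    if not np.isfinite(runs["lnP"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite lnP values")
    ks = np.sort(runs["K"].unique())
    if len(ks) < 3:
        raise ValueError(f"need >= 3 K values for interior delta-K, got {len(ks)}")
    if not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise ValueError(f"K values must be contiguous, got {list(ks)}")
    grouped = runs.groupby("K")["lnP"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 runs per K for sd; K={bad} have fewer")
    mean = grouped.mean().reindex(ks).to_numpy()
    sd = grouped.std(ddof=1).reindex(ks).to_numpy()
    rows = []
    for i, k in enumerate(ks):
        lprime = mean[i] - mean[i - 1] if i >= 1 else np.nan
        lprime_next = mean[i + 1] - mean[i] if i + 1 < len(ks) else np.nan
        lsecond = abs(lprime_next - lprime) if i >= 1 and i + 1 < len(ks) else np.nan
        if not np.isnan(lsecond) and sd[i] == 0:
            warnings.warn(f"sd(lnP) = 0 at K={k}; delta-K undefined there")
            dk = np.nan
        else:
            dk = lsecond / sd[i] if not np.isnan(lsecond) else np.nan
        rows.append(
            {
                "K": int(k),
                "mean_lnP": mean[i],
                "sd_lnP": sd[i],
                "lprime": lprime,
                "lsecond": lsecond,
                "delta_k": dk,
            }
        )
    table = pd.DataFrame(rows)
    dk_vals = table["delta_k"]
    selected = None
    if dk_vals.notna().any():
        selected = int(table.loc[dk_vals.idxmax(), "K"])
    return DeltaKTable(table=table, selected_k=selected)


# ---------------------------------------------------------------------------
# Q-matrix handling
# ---------------------------------------------------------------------------

def read_qmatrix(path) -> pd.DataFrame:
    """Read a Q-matrix CSV: ``sample_id`` then one probability column per
    cluster (``q1..qK``), each row summing to 1."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("Q-matrix lacks a sample_id column")
    return df.set_index("sample_id")


def _validate_q(q: pd.DataFrame, tol: float = 1e-6) -> np.ndarray:
    M = q.to_numpy(dtype=float)
    if M.ndim != 2 or M.shape[1] < 1:
        raise ValueError("Q-matrix must have at least one cluster column")
    if (M < -tol).any() or (M > 1 + tol).any():
        raise ValueError("Q-matrix entries must lie in [0, 1]")
    sums = M.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tol)
    if len(bad):
        raise ValueError(
            f"Q-matrix rows do not sum to 1 within {tol}: row(s) {bad[:5].tolist()}"
        )
    return M


def modal_assignment(q: pd.DataFrame) -> pd.Series:
    """Hard cluster labels: the argmax column of each Q-matrix row.

    Ties break to the lowest cluster index.  Labels are 1-based cluster
    numbers, indexed by sample id.
    """
    M = _validate_q(q)
    labels = M.argmax(axis=1) + 1  # argmax takes the first maximum: low-index tie-break
    return pd.Series(labels, index=q.index, name="cluster")


def coassignment_chi_square(
    n_pairs: int, n_coassigned: int, expected_prop: float
) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square on the co-assigned / not-co-assigned
    split of same-block pairs; returns (chi_sq, upper-tail p)."""
    N, O = n_pairs, n_coassigned
    E = expected_prop * N
    if E < 1 or (N - E) < 1:
        warnings.warn("expected count below 1; chi-square approximation unreliable")
    if E == 0 or E == N:
        return 0.0, 1.0
    chi = (O - E) ** 2 / E + ((N - O) - (N - E)) ** 2 / (N - E)
    return float(chi), float(stats.chi2.sf(chi, df=1))


@dataclass
class CoassignmentResult:
    """Same-block co-assignment versus the random-label expectation."""

    n_same_block_pairs: int
    observed_prop: float
    expected_prop: float
    chi_sq: float
    df: int
    p_value: float


def coassignment_test(labels: pd.Series | Sequence, ds: MicrosatDataset) -> CoassignmentResult:
    """Test whether same-block samples share a cluster more than chance.

    ``labels`` is one hard label per sample (a Series indexed by sample id,
    or a sequence in dataset order).  The expectation is sum_k q_k^2 over
    the overall label frequencies q_k.
    """
    if isinstance(labels, pd.Series):
        try:
            lab = np.asarray([labels.loc[s.sample_id] for s in ds.samples])
        except KeyError as e:
            raise ValueError(f"labels missing sample {e}") from None
    else:
        lab = np.asarray(list(labels))
        if len(lab) != ds.n_samples:
            raise ValueError(
                f"{len(lab)} labels for {ds.n_samples} samples"
            )
    blocks = []
    for s in ds.samples:
        if s.block_id is None:
            raise MissingMetadataError(f"sample {s.sample_id!r} has no block_id")
        blocks.append(s.block_id)
    blocks = np.asarray(blocks)
    if len(np.unique(lab)) < 2:
        # single represented cluster: every pair co-assigned, trivially equal
        # to expectation; degenerate by construction
        same_pairs = sum(
            1 for i, j in combinations(range(len(blocks)), 2) if blocks[i] == blocks[j]
        )
        if same_pairs == 0:
            raise ValueError("no same-block pairs in dataset")
        return CoassignmentResult(same_pairs, 1.0, 1.0, 0.0, 1, 1.0)
    n = len(blocks)
    same_mask_pairs = 0
    co_assigned = 0
    # same-block pairs only; O(n^2) over <= a few hundred samples
    for i in range(n):
        for j in range(i + 1, n):
            if blocks[i] == blocks[j]:
                same_mask_pairs += 1
                if lab[i] == lab[j]:
                    co_assigned += 1
    if same_mask_pairs == 0:
        raise ValueError("no same-block pairs in dataset")
    _, freq = np.unique(lab, return_counts=True)
    qk = freq / n
    expected_prop = float(np.sum(qk**2))
    N = same_mask_pairs
    O = co_assigned
    chi, p = coassignment_chi_square(N, O, expected_prop)
    return CoassignmentResult(
        n_same_block_pairs=N,
        observed_prop=O / N,
        expected_prop=expected_prop,
        chi_sq=float(chi),
        df=1,
        p_value=p,
    )
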