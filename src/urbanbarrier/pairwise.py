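"""Pairwise genetic dissimilarity, spatial distance, and design indicators.

Genetic distance between two diploid multilocus genotypes is the
Bray-Curtis dissimilarity of their pooled allele-count vectors: each locus
contributes two counts per individual, loci missing in either member of a
pair are dropped for that pair only, and

    BC = 1 - 2 * sum_a min(c_i,a, c_j,a) / (sum_a c_i,a + sum_a c_j,a)

over the alleles *a* of the shared loci.  BC is 0 iff the two genotypes
carry identical allele multisets on their shared loci and 1 when they
share no allele; it is symmetric but not a metric (no triangle
inequality).

:func:`build_pair_table` assembles every unordered sample pair with its
genetic distance, planar Euclidean distance in meters, and the two design
indicators the regression uses — ``cross_block`` (1 = different city
block) and ``cross_year`` (1 = different collection year), so positive
regression coefficients mean more dissimilar across streets / years.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import MicrosatDataset, MissingMetadataError, SampleRecord

__all__ = [
    "NoSharedLociError",
    "PairTable",
    "bray_curtis",
    "euclidean",
    "build_pair_table",
    "genetic_distance_matrix",
]

logger = logging.getLogger(__name__)

#: columns of the pair table, in on-disk order
PAIR_COLUMNS = [
    "id_i", "id_j", "genetic_d", "euclid_m", "cross_block", "cross_year", "n_loci_used",
]


class NoSharedLociError(ValueError):
    """A sample pair has no locus typed in both members; it must be dropped
    upstream, never silently scored 0."""


def bray_curtis(geno_i, geno_j) -> float:
    """Bray-Curtis dissimilarity between two multilocus genotypes.

    Arguments are per-locus genotype tuples as stored on
    :class:`~urbanbarrier.genotype_io.SampleRecord` (``None`` = missing
    locus).  Only loci non-missing in both genotypes contribute.
    """
    if len(geno_i) != len(geno_j):
        raise ValueError("genotypes must cover the same locus list")
    shared = 0
    num = 0
    total = 0
    for k, (gi, gj) in enumerate(zip(geno_i, geno_j)):
        if gi is None or gj is None:
            continue
        shared += 1
        # allele keyed per locus so identical sizes at different loci never pool
        ci = Counter((k, a) for a in gi)
        cj = Counter((k, a) for a in gj)
        num += sum(min(ci[a], cj[a]) for a in ci)
        total += 4  # 2 allele counts per diploid genotype per side
    if shared == 0:
        raise NoSharedLociError("pair shares no non-missing locus")
    return 1.0 - 2.0 * num / total


def euclidean(s_i: SampleRecord, s_j: SampleRecord) -> float:
    """Planar Euclidean distance in meters between two samples."""
    if not (s_i.has_coordinates and s_j.has_coordinates):
        missing = s_i.sample_id if not s_i.has_coordinates else s_j.sample_id
        raise MissingMetadataError(f"sample {missing!r} has no coordinates")
    return float(np.hypot(s_i.x - s_j.x, s_i.y - s_j.y))


# ---------------------------------------------------------------------------
# vectorized distance matrix (drives the pair table and the permutation test)
# ---------------------------------------------------------------------------

def _allele_count_blocks(ds: MicrosatDataset):
    """Per-locus allele-count matrices and the typed-locus mask.

    Returns ``(counts, typed)`` where ``counts`` is a list of (n, A_l)
    integer matrices (two counts per typed individual per locus) and
    ``typed`` is an (n, L) boolean matrix of locus presence.
    """
    n, L = ds.n_samples, ds.n_loci
    typed = np.zeros((n, L), dtype=bool)
    counts = []
    for l in range(L):
        alleles = sorted(
            {a for s in ds.samples if s.genotype[l] is not None for a in s.genotype[l]}
        )
        index = {a: k for k, a in enumerate(alleles)}
        C = np.zeros((n, max(len(alleles), 1)), dtype=np.int16)
        for i, s in enumerate(ds.samples):
            g = s.genotype[l]
            if g is None:
                continue
            typed[i, l] = True
            C[i, index[g[0]]] += 1
            C[i, index[g[1]]] += 1
        counts.append(C)
    return counts, typed


def genetic_distance_matrix(ds: MicrosatDataset) -> tuple[np.ndarray, np.ndarray]:
    """Full n x n Bray-Curtis matrix and the shared-locus count matrix.

    Entries with zero shared loci are NaN.  The permutation test exploits
    the fact that permuting whole genotypes among samples is a relabeling
    of this matrix's rows and columns.
    """
    counts, typed = _allele_count_blocks(ds)
    n, L = typed.shape
    num = np.zeros((n, n))
    shared = typed.astype(np.int64) @ typed.astype(np.int64).T
    for l in range(L):
        C = counts[l].astype(np.int64)
        # sum over alleles of pairwise minima; loci untyped on either side
        # contribute zero counts so the typed mask handles exclusion
        minsum = np.zeros((n, n), dtype=np.int64)
        for a in range(C.shape[1]):
            minsum += np.minimum.outer(C[:, a], C[:, a])
        both = np.outer(typed[:, l], typed[:, l])
        num += np.where(both, minsum, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - 2.0 * num / (4.0 * shared)
    D[shared == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    untyped = np.flatnonzero(~typed.any(axis=1))
    D[untyped, untyped] = np.nan
    return D, shared


@dataclass
class PairTable:
    """All unordered sample pairs with distances and design indicators.

    ``df`` holds one row per retained pair (columns ``PAIR_COLUMNS``);
    ``n_excluded`` counts pairs dropped for sharing no typed locus.
    """

    df: pd.DataFrame
    dataset: Optional[MicrosatDataset] = None
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.df)

    def same_block(self) -> pd.DataFrame:
        return self.df[self.df["cross_block"] == 0]

    def cross_block(self) -> pd.DataFrame:
        return self.df[self.df["cross_block"] == 1]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PairTable":
        df = pd.read_csv(path)
        missing = set(PAIR_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"pair table lacks columns {sorted(missing)}")
        return cls(df=df[PAIR_COLUMNS])


def build_pair_table(
    ds: MicrosatDataset, within_year: bool = False
) -> PairTable:
    """Build the n(n-1)/2 pair table from a dataset.

    ``within_year=True`` restricts to pairs collected the same year (an
    optional variant some analyses use); the default keeps every pair.
    Pairs with no shared typed locus are excluded with a logged count.
    """
    n = ds.n_samples
    if n < 2:
        raise ValueError(f"need at least 2 samples to form pairs, got {n}")
    for s in ds.samples:
        if not s.has_coordinates:
            raise MissingMetadataError(f"sample {s.sample_id!r} has no coordinates")
        if s.block_id is None:
            raise MissingMetadataError(f"sample {s.sample_id!r} has no block_id")
        if s.year is None:
            raise MissingMetadataError(f"sample {s.sample_id!r} has no year")
    D, shared = genetic_distance_matrix(ds)
    xy = np.array([[s.x, s.y] for s in ds.samples])
    diff = xy[:, None, :] - xy[None, :, :]
    E = np.sqrt((diff**2).sum(axis=2))
    blocks = np.array([s.block_id for s in ds.samples])
    years = np.array([s.year for s in ds.samples])
    ii, jj = np.triu_indices(n, k=1)
    keep = shared[ii, jj] >= 1
    if within_year:
        keep &= years[ii] == years[jj]
    n_excluded = int((shared[ii, jj] < 1).sum())
    if n_excluded:
        logger.warning("excluded %d pairs sharing no typed locus", n_excluded)
    ii, jj = ii[keep], jj[keep]
    ids = np.array(ds.sample_ids)
    df = pd.DataFrame(
        {
            "id_i": ids[ii],
            "id_j": ids[jj],
            "genetic_d": D[ii, jj],
            "euclid_m": E[ii, jj],
            "cross_block": (blocks[ii] != blocks[jj]).astype(int),
            "cross_year": (years[ii] != years[jj]).astype(int),
            "n_loci_used": shared[ii, jj].astype(int),
        }
    )
    return PairTable(df=df, dataset=ds, n_excluded=n_excluded)
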