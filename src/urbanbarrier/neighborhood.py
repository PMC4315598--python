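"""Sliding-neighborhood genetic diversity along the transect.

Every sample is the center of a circular neighborhood of a given radius;
all samples within the radius (the focal individual included) form the
local population for which observed heterozygosity (Ho), Nei's unbiased
expected heterozygosity (He), the inbreeding coefficient F_IS = 1 -
mean(Ho_l)/mean(He_l), and rarefied allelic richness (AR) are computed.
Neighborhoods holding fewer than ``min_n`` samples are flagged invalid and
carry no indices.

Per locus *l* with ``n_l`` typed individuals (2 n_l gene copies):

* ``Ho_l`` — fraction of heterozygous individuals;
* ``He_l = (2 n_l / (2 n_l - 1)) * (1 - sum_a p_a^2)`` (small-sample
  corrected);
* ``AR_l = sum_a [1 - C(2 n_l - N_a, g') / C(2 n_l, g')]`` — the expected
  number of distinct alleles in a hypergeometric subsample of ``g' = 2 g``
  gene copies, with ``N_a`` the copies of allele *a*.

Sample-level values average the loci typed in at least ``g`` individuals,
so every valid neighborhood is rarefied to the same number of gene copies.

The candidate radius is chosen where the count of valid neighborhoods
levels off (first relative increase below a threshold), and each index can
be regressed against the transect's horizontal coordinate to detect
founder-wave trends.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.spatial import cKDTree

from .genotype_io import MicrosatDataset, MissingMetadataError

__all__ = [
    "NeighborhoodIndex",
    "RadiusScan",
    "TrendFit",
    "neighborhood_indices",
    "select_radius",
    "levels_off_selection",
    "longitudinal_trend",
]

INDEX_NAMES = ("ho", "f_is", "ar")


@dataclass
class NeighborhoodIndex:
    """Diversity indices of one sample's neighborhood.

    Indices are ``None`` when the neighborhood is invalid (fewer than
    ``min_n`` samples) or, for ``f_is``, when the neighborhood is
    monomorphic at every retained locus (He = 0).
    """

    sample_id: str
    n_neighbors: int
    ho: Optional[float]
    he: Optional[float]
    f_is: Optional[float]
    ar: Optional[float]
    valid: bool


@dataclass
class RadiusScan:
    """Valid-neighborhood counts per candidate radius and the selection."""

    radii: list[float]
    valid_counts: list[int]
    selected: float
    threshold: float


@dataclass
class TrendFit:
    """OLS trend of a neighborhood index against transect position x."""

    index_name: str
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int


def _locus_stats(genos: list, g_prime: int):
    """(Ho, He, AR, n_typed) for one locus of one neighborhood."""
    typed = [g for g in genos if g is not None]
    n = len(typed)
    if n == 0:
        return None
    two_n = 2 * n
    ho = sum(1 for a, b in typed if a != b) / n
    counts: dict[int, int] = {}
    for a, b in typed:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    sum_p2 = sum((c / two_n) ** 2 for c in counts.values())
    he = (two_n / (two_n - 1)) * (1.0 - sum_p2) if two_n > 1 else 0.0
    denom = math.comb(two_n, g_prime) if g_prime <= two_n else 0
    if denom == 0:
        ar = float(len(counts))  # g' exceeds the sample: no rarefaction possible
    else:
        ar = 0.0
        for c in counts.values():
            absent = math.comb(two_n - c, g_prime) if g_prime <= two_n - c else 0
            ar += 1.0 - absent / denom
    return ho, he, ar, n


def neighborhood_indices(
    ds: MicrosatDataset,
    radius: float,
    min_n: int = 10,
    rarefaction_g: int = 10,
    year: Optional[int] = None,
) -> list[NeighborhoodIndex]:
    """Per-sample neighborhood diversity indices at one radius.

    ``year`` restricts both focal samples and their neighborhoods to one
    collection year (the per-year analysis); the default pools years.
    Loci typed in fewer than ``rarefaction_g`` individuals of a
    neighborhood are dropped from that neighborhood's means.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if min_n < 2:
        raise ValueError(f"min_n must be >= 2, got {min_n}")
    if rarefaction_g < 1:
        raise ValueError(f"rarefaction_g must be >= 1, got {rarefaction_g}")
    samples = [
        s for s in ds.samples if year is None or s.year == year
    ]
    if not samples:
        raise ValueError(f"no samples in year {year}")
    for s in samples:
        if not s.has_coordinates:
            raise MissingMetadataError(f"sample {s.sample_id!r} has no coordinates")
    xy = np.array([[s.x, s.y] for s in samples])
    tree = cKDTree(xy)
    g_prime = 2 * rarefaction_g
    out: list[NeighborhoodIndex] = []
    neighbor_lists = tree.query_ball_point(xy, r=radius)
    for i, s in enumerate(samples):
        nbr = neighbor_lists[i]
        n_nbr = len(nbr)  # self always included (distance 0)
        if n_nbr < min_n:
            out.append(NeighborhoodIndex(s.sample_id, n_nbr, None, None, None, None, False))
            continue
        hos, hes, ars = [], [], []
        for l in range(ds.n_loci):
            res = _locus_stats([samples[j].genotype[l] for j in nbr], g_prime)
            if res is None:
                continue
            ho_l, he_l, ar_l, n_l = res
            if n_l < rarefaction_g:
                continue  # below the rarefaction standard; not comparable
            hos.append(ho_l)
            hes.append(he_l)
            ars.append(ar_l)
        if not hos:
            warnings.warn(
                f"sample {s.sample_id!r}: no locus typed in >= {rarefaction_g} "
                "neighbors; neighborhood marked invalid"
            )
            out.append(NeighborhoodIndex(s.sample_id, n_nbr, None, None, None, None, False))
            continue
        ho = float(np.mean(hos))
        he = float(np.mean(hes))
        if he == 0.0:
            warnings.warn(
                f"sample {s.sample_id!r}: neighborhood monomorphic at every "
                "retained locus (He = 0); F_IS undefined"
            )
            f_is = None
        else:
            f_is = float(1.0 - ho / he)
        out.append(
            NeighborhoodIndex(
                s.sample_id, n_nbr, ho, he, f_is, float(np.mean(ars)), True
            )
        )
    return out


def levels_off_selection(
    radii: Sequence[float], counts: Sequence[int], threshold: float = 0.05
) -> Optional[float]:
    """The smallest radius whose relative gain in valid count over the
    previous radius drops below ``threshold``; None if it never does."""
    for k in range(1, len(radii)):
        prev, cur = counts[k - 1], counts[k]
        rel = 0.0 if cur == prev else (math.inf if prev == 0 else (cur - prev) / prev)
        if rel < threshold:
            return float(radii[k])
    return None


def select_radius(
    ds: MicrosatDataset,
    radii: Sequence[float] = (100, 125, 150, 175, 200, 225, 250),
    min_n: int = 10,
    threshold: float = 0.05,
    year: Optional[int] = None,
) -> RadiusScan:
    """Pick the radius where the number of valid neighborhoods levels off.

    The selected radius is the smallest whose relative increase in valid
    count over the previous radius falls below ``threshold``; if the
    counts never level off the largest radius is returned with a warning.
    """
    radii = [float(r) for r in radii]
    if len(radii) < 2 or any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly increasing with >= 2 entries")
    samples = [s for s in ds.samples if year is None or s.year == year]
    if not samples:
        raise ValueError("empty dataset")
    for s in samples:
        if not s.has_coordinates:
            raise MissingMetadataError(f"sample {s.sample_id!r} has no coordinates")
    xy = np.array([[s.x, s.y] for s in samples])
    tree = cKDTree(xy)
    counts = []
    for r in radii:
        n_nbrs = tree.query_ball_point(xy, r=r, return_length=True)
        counts.append(int(np.sum(n_nbrs >= min_n)))
    selected = levels_off_selection(radii, counts, threshold)
    if selected is None:
        warnings.warn(
            "valid-sample counts never level off over the candidate radii; "
            "falling back to the largest radius"
        )
        selected = radii[-1]
    return RadiusScan(radii=radii, valid_counts=counts, selected=selected, threshold=threshold)


def longitudinal_trend(
    indices: list[NeighborhoodIndex],
    ds: MicrosatDataset,
    index_name: str,
) -> TrendFit:
    """OLS regression of a neighborhood index on transect position x."""
    if index_name not in INDEX_NAMES:
        raise ValueError(f"index_name must be one of {INDEX_NAMES}, got {index_name!r}")
    x_by_id = {s.sample_id: s.x for s in ds.samples}
    xs, ys = [], []
    for idx in indices:
        if not idx.valid:
            continue
        val = getattr(idx, index_name)
        if val is None:
            continue
        x = x_by_id.get(idx.sample_id)
        if x is None:
            raise MissingMetadataError(f"sample {idx.sample_id!r} has no x coordinate")
        xs.append(x)
        ys.append(val)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 valid samples for a trend fit, got {len(xs)}")
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if np.ptp(xs) == 0:
        raise ValueError("all x positions identical; trend undefined")
    X = sm.add_constant(xs)
    res = sm.OLS(ys, X).fit()
    return TrendFit(
        index_name=index_name,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        n=len(xs),
    )
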