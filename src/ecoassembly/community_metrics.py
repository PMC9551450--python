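"""Beta-diversity, geographic/environmental distances, distance decay, and
Levins niche breadth.

Distance-decay fits regress pairwise community similarity (1 - Bray-Curtis)
on great-circle distance; significance comes from a sample-label permutation
test because pair observations are not independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .data_model import DistanceMatrix, OtuTable, SampleMetadata, ValidationError

EARTH_RADIUS_KM = 6371.0088


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(a, b) = 1 - 2 * sum_j min(a_j, b_j) / (sum_j a_j + sum_j b_j).
    """
    if table.n_samples < 2:
        raise ValidationError("need at least two samples")
    totals = table.sample_totals()
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValidationError(f"all-zero samples: {zero}")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, list(table.sample_ids), "bray_curtis")


def geographic_distance(meta: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from latitude/longitude."""
    for col in ("latitude", "longitude"):
        if col not in meta.data.columns:
            raise ValidationError(f"metadata missing {col!r}")
        if meta.data[col].isna().any():
            raise ValidationError(f"missing values in {col!r}")
    lat = np.radians(meta.data["latitude"].to_numpy(float))
    lon = np.radians(meta.data["longitude"].to_numpy(float))
    if np.any(np.abs(meta.data["latitude"].to_numpy(float)) > 90):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any(np.abs(meta.data["longitude"].to_numpy(float)) > 180):
        raise ValidationError("longitude outside [-180, 180]")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, meta.sample_ids, "geographic_km")


def environmental_distance(meta: SampleMetadata, variables: list[str]) -> DistanceMatrix:
    """Euclidean distance on z-scored (mean 0, sd 1 with n-1) variables."""
    for v in variables:
        if v not in meta.data.columns:
            raise ValidationError(f"metadata missing variable {v!r}")
    x = meta.data[list(variables)].to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    zero_var = [v for v, s in zip(variables, sd) if s == 0]
    if zero_var:
        raise ValidationError(f"zero-variance variables: {zero_var}")
    z = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(z, metric="euclidean"))
    return DistanceMatrix(d, meta.sample_ids, "environment_euclidean")


def variable_difference_distance(meta: SampleMetadata, variable: str) -> DistanceMatrix:
    """|x_i - x_j| matrix for a single environmental variable."""
    if variable not in meta.data.columns:
        raise ValidationError(f"metadata missing variable {variable!r}")
    x = meta.data[variable].to_numpy(float)
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(d, meta.sample_ids, f"abs_diff_{variable}")


@dataclass
class DdrFit:
    """Distance-decay regression of similarity on geographic distance."""

    slope: float  # similarity per km
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int
    n_perm: int = 0


def distance_decay(
    community_dist: DistanceMatrix,
    geo_dist: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> DdrFit:
    """OLS of (1 - dissimilarity) on distance over all unordered pairs.

    The p-value is a two-sided sample-label permutation test on the slope
    (labels of the community matrix are permuted jointly, ``n_perm`` times).
    """
    if community_dist.labels != geo_dist.labels:
        geo_dist = geo_dist.reordered(community_dist.labels)
    n = community_dist.n
    if n < 3:
        raise ValidationError("need at least three samples")
    x = geo_dist.condensed()
    if np.ptp(x) == 0:
        raise ValidationError("constant geographic distances")
    sim_matrix = 1.0 - community_dist.values
    iu = np.triu_indices(n, k=1)
    y = sim_matrix[iu]

    res = stats.linregress(x, y)
    slope_obs = float(res.slope)

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom = float(xc @ xc)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = sim_matrix[np.ix_(perm, perm)][iu]
        slope_p = float(xc @ (yp - yp.mean())) / denom
        if abs(slope_p) >= abs(slope_obs):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return DdrFit(
        slope=slope_obs,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=p,
        n_pairs=len(y),
        n_perm=n_perm,
    )


@dataclass
class NicheBreadthResult:
    """Levins breadth per OTU and abundance-weighted community means."""

    B: dict[str, float]
    Bcom: dict[str, float]


def levins_breadth(table: OtuTable) -> NicheBreadthResult:
    """Levins breadth B_j = 1 / sum_i P_ij^2 with P the OTU's cross-sample
    abundance profile; Bcom_k is the abundance-weighted mean B over the OTUs
    present in sample k (weights renormalized within the sample)."""
    totals = table.otu_totals()
    zero = [o for o, t in zip(table.otu_ids, totals) if t == 0]
    if zero:
        raise ValidationError(f"zero-total OTUs (filter first): {zero[:5]}")
    p = table.counts / totals[None, :]
    b = 1.0 / (p**2).sum(axis=0)
    n_k = table.sample_totals().astype(float)
    bcom = (table.counts * b[None, :]).sum(axis=1) / n_k
    return NicheBreadthResult(
        B=dict(zip(table.otu_ids, b.astype(float))),
        Bcom=dict(zip(table.sample_ids, bcom.astype(float))),
    )


@dataclass
class GroupComparison:
    statistic: float
    p_value: float


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) with normal approximation
    and tie correction."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(statistic=float(res.statistic), p_value=float(res.pvalue))
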