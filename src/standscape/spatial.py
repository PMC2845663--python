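"""Spatial genetic structure: Mantel tests, Moran's I correlograms,
Gregorius-distance distograms, nearest-neighbor aggregation, and
within-stand transect clustering statistics.

Between-stand structure is profiled with distance-class correlograms: for
each class of pairwise geographic distance, an autocorrelation statistic
(Moran's I on per-individual allele-frequency scores, averaged over loci)
or the class-mean genetic distance (Gregorius D_G) is compared with a
permutation envelope obtained by shuffling individuals over the sampled
locations.  Within stands sampled along a line, clustering of identical
multilocus genotypes is summarized by C2 (proportion of plants with at
least one identical neighbor) and C3 (proportion of interior plants
flanked by two identical neighbors).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .core import MISSING

__all__ = [
    "DistanceClassSpec",
    "CorrelogramResult",
    "MantelResult",
    "AggregationResult",
    "TransectStats",
    "mantel_test",
    "morans_i_correlogram",
    "dg_distogram",
    "gregorius_distance_matrix",
    "aggregation_index",
    "transect_clustering",
    "cluster_vs_fis_regression",
]


@dataclass(frozen=True)
class DistanceClassSpec:
    """Contiguous distance classes from zero: ``n_classes`` of ``width`` km."""

    n_classes: int
    class_width_km: float

    def __post_init__(self):
        if self.n_classes < 1 or self.class_width_km <= 0:
            raise ValueError("need >= 1 class of positive width")

    @property
    def upper_bounds_km(self) -> np.ndarray:
        return self.class_width_km * np.arange(1, self.n_classes + 1)

    def classify(self, dist_km: np.ndarray) -> np.ndarray:
        """Class index per distance; -1 for beyond the last bound."""
        idx = np.floor(dist_km / self.class_width_km).astype(int)
        idx[idx >= self.n_classes] = -1
        return idx


@dataclass
class CorrelogramResult:
    statistic: str  # "morans_i" or "d_g"
    class_upper_km: np.ndarray
    values: np.ndarray  # per-class statistic (NaN for empty class)
    n_pairs: np.ndarray
    perm_mean: np.ndarray
    env_low: np.ndarray
    env_high: np.ndarray
    significant: np.ndarray  # outside the 95% envelope


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int


def _check_square(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    return m


def mantel_test(
    genetic: np.ndarray,
    geographic: np.ndarray,
    n_perms: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    The statistic is the Pearson correlation of the off-diagonal entries;
    significance is one-sided (isolation by distance predicts positive
    correlation) via joint row/column label permutation, with
    p = (#{perm r >= observed} + 1) / (n_perms + 1).
    """
    g = _check_square(genetic, "genetic matrix")
    d = _check_square(geographic, "geographic matrix")
    if g.shape != d.shape:
        raise ValueError("matrices must have matching shape")
    n = g.shape[0]
    iu = np.triu_indices(n, 1)
    x, y = g[iu], d[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance distance matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(n)
        xp = g[np.ix_(perm, perm)][iu]
        if float(np.corrcoef(xp, y)[0, 1]) >= r_obs:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perms + 1), n_perms)


# ---------------------------------------------------------------------------
# correlogram / distogram machinery
# ---------------------------------------------------------------------------


def _pair_classes(coords: np.ndarray, spec: DistanceClassSpec):
    """Upper-triangle pair indices grouped by distance class."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    d_km = pdist(coords) / 1000.0
    iu = np.triu_indices(n, 1)
    cls = spec.classify(d_km)
    groups = []
    for c in range(spec.n_classes):
        sel = cls == c
        groups.append((iu[0][sel], iu[1][sel]))
    return groups


def _scores(calls: np.ndarray) -> np.ndarray:
    """Per-individual allele-b frequency scores (0, .5, 1); NaN if missing."""
    y = np.asarray(calls, dtype=float) / 2.0
    y[np.asarray(calls) == MISSING] = np.nan
    return y


def _morans_per_class(y: np.ndarray, groups) -> np.ndarray:
    """Mean-over-loci Moran's I per distance class with binary weights.

    Per-allele scores enter with equal weight; for biallelic markers the
    two alleles give identical I (affine invariance), so each polymorphic
    marker contributes once.
    """
    n, L = y.shape
    mean = np.nanmean(y, axis=0)
    z = y - mean[None, :]
    z = np.nan_to_num(z, nan=0.0)  # missing contributes nothing
    denom = (z**2).sum(axis=0)
    poly = denom > 0
    out = np.full(len(groups), np.nan)
    for c, (i_idx, j_idx) in enumerate(groups):
        if i_idx.size == 0 or not poly.any():
            continue
        cross = (z[i_idx] * z[j_idx]).sum(axis=0)  # per locus, unordered pairs
        # I = n * sum_w z_i z_j / (W * sum z^2); W = 2 * n_pairs (symmetric)
        i_vals = n * 2.0 * cross[poly] / (2.0 * i_idx.size * denom[poly])
        out[c] = i_vals.mean()
    return out


def _dg_per_class(y: np.ndarray, groups) -> np.ndarray:
    out = np.full(len(groups), np.nan)
    for c, (i_idx, j_idx) in enumerate(groups):
        if i_idx.size == 0:
            continue
        diff = np.abs(y[i_idx] - y[j_idx])  # (pairs, loci); NaN where missing
        dg = np.nanmean(diff, axis=1)  # Gregorius distance per pair
        out[c] = float(np.nanmean(dg))
    return out


def _correlogram(
    calls, coords, spec, n_perms, seed, stat_fn, name
) -> CorrelogramResult:
    calls = np.atleast_2d(np.asarray(calls))
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != calls.shape[0] or coords.shape[0] < 2:
        raise ValueError("need coordinates for every individual (>= 2)")
    y = _scores(calls)
    if np.all(np.nanstd(y, axis=0) == 0):
        raise ValueError("no polymorphic marker: statistic undefined")
    groups = _pair_classes(coords, spec)
    observed = stat_fn(y, groups)
    rng = np.random.default_rng(seed)
    perms = np.full((n_perms, spec.n_classes), np.nan)
    for r in range(n_perms):
        perm = rng.permutation(calls.shape[0])
        perms[r] = stat_fn(y[perm], groups)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # empty distance classes are legitimately all-NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(perms, axis=0)
        low = np.nanpercentile(perms, 2.5, axis=0)
        high = np.nanpercentile(perms, 97.5, axis=0)
    n_pairs = np.array([g[0].size for g in groups])
    sig = (observed < low) | (observed > high)
    sig &= ~np.isnan(observed)
    return CorrelogramResult(
        name, spec.upper_bounds_km, observed, n_pairs, mean, low, high, sig
    )


def morans_i_correlogram(
    calls: np.ndarray,
    coords: np.ndarray,
    spec: DistanceClassSpec,
    n_perms: int = 500,
    seed: int | None = None,
) -> CorrelogramResult:
    """Moran's I spatial autocorrelation per geographic distance class.

    Pairs within a class receive equal (binary) weight; the statistic is
    averaged over polymorphic loci; the envelope comes from ``n_perms``
    permutations of individuals across the sampled locations.
    """
    return _correlogram(calls, coords, spec, n_perms, seed, _morans_per_class, "morans_i")


def dg_distogram(
    calls: np.ndarray,
    coords: np.ndarray,
    spec: DistanceClassSpec,
    n_perms: int = 500,
    seed: int | None = None,
) -> CorrelogramResult:
    """Class-mean Gregorius genetic distance D_G with permutation envelope.

    D_G between two individuals is the mean over loci of half the summed
    absolute difference of their allele frequencies; for biallelic dosages
    this is |y_i - y_j| with y the allele-b score (0, 1/2, 1).
    """
    return _correlogram(calls, coords, spec, n_perms, seed, _dg_per_class, "d_g")


def gregorius_distance_matrix(calls: np.ndarray) -> np.ndarray:
    """Full pairwise Gregorius D_G matrix (NaN-aware over missing calls)."""
    y = _scores(calls)
    n = y.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(y[i + 1 :] - y[i][None, :])
        d = np.nanmean(diff, axis=1)
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


@dataclass
class AggregationResult:
    r: float  # observed mean NN distance / CSR expectation
    n_points: int
    area: float
    p_value: float  # Monte-Carlo, one-sided toward clumping (R < 1)


def aggregation_index(
    coords: np.ndarray,
    area: float,
    n_sims: int = 199,
    seed: int | None = None,
) -> AggregationResult:
    """Clark-Evans aggregation index R with Monte-Carlo CSR significance.

    R = (mean nearest-neighbor distance) / (0.5 / sqrt(n / area)); R < 1
    indicates clumping, R = 0 complete coincidence.  The null simulates
    complete spatial randomness in a square of the same area.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if area <= 0:
        raise ValueError("area must be positive")

    def mean_nn(pts: np.ndarray) -> float:
        d = squareform(pdist(pts))
        np.fill_diagonal(d, np.inf)
        return float(d.min(axis=1).mean())

    expected = 0.5 / math.sqrt(n / area)
    r_obs = mean_nn(coords) / expected
    rng = np.random.default_rng(seed)
    side = math.sqrt(area)
    count = 0
    for _ in range(n_sims):
        pts = rng.uniform(0, side, size=(n, 2))
        if mean_nn(pts) / expected <= r_obs:
            count += 1
    return AggregationResult(r_obs, n, area, (count + 1) / (n_sims + 1))


# ---------------------------------------------------------------------------
# within-stand transects
# ---------------------------------------------------------------------------


@dataclass
class TransectStats:
    stand_id: str
    n: int
    c2: float  # proportion of plants with >= 1 identical neighbor
    c3: float  # proportion of interior plants flanked by two identical neighbors


def transect_clustering(mlg_sequence, stand_id: str = "") -> TransectStats:
    """C2/C3 genotype-clustering statistics along a sampling transect.

    ``mlg_sequence`` lists MLG labels in transect order.  C2 is computed
    over all n plants (ends have a single neighbor); C3 only over the n-2
    interior plants.  Both equal 1 iff the transect is monotypic.
    """
    seq = list(mlg_sequence)
    n = len(seq)
    if n < 3:
        raise ValueError("need at least 3 plants along the transect")
    c2_hits = sum(
        1
        for i in range(n)
        if (i > 0 and seq[i - 1] == seq[i]) or (i < n - 1 and seq[i + 1] == seq[i])
    )
    c3_hits = sum(
        1 for i in range(1, n - 1) if seq[i - 1] == seq[i] == seq[i + 1]
    )
    return TransectStats(stand_id, n, c2_hits / n, c3_hits / (n - 2))


def cluster_vs_fis_regression(
    cluster_values: np.ndarray, f_is_values: np.ndarray
) -> dict:
    """OLS of F_IS on a transect clustering statistic (C2 or C3).

    Returns slope, intercept, Pearson r, r^2 and the two-sided p-value.
    Tests whether within-stand spatial structure predicts homozygosity
    (a Wahlund-type signal).
    """
    x = np.asarray(cluster_values, dtype=float)
    y = np.asarray(f_is_values, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 stands with both statistics")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "r2": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(x.size),
    }
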