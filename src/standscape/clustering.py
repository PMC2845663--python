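"""Pairwise genetic distances, nonparametric clustering with gap-statistic
model selection, and group comparisons of stand statistics.

The individual-level distance is the allele-sharing distance
d = 1 - (mean over jointly called loci of shared alleles / 2): 0 for
identical genotypes, 1 for opposite homozygotes everywhere.  Because the
study species violates assumptions of model-based ancestry methods (free
outcrossing, Hardy-Weinberg), clustering is nonparametric: agglomerative
hierarchical trees on the distance matrix, with the number of clusters
chosen by the gap statistic against a frequency-preserving reference null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import MISSING, GenotypeTable, MLGTable

__all__ = [
    "allele_sharing_distance",
    "allele_sharing_matrix",
    "Dendrogram",
    "cluster_genotypes",
    "GapResult",
    "gap_statistic",
    "within_between_distributions",
    "GroupComparison",
    "compare_site_types",
    "nonredundant_mlg_table",
    "write_phylip_square",
]


def allele_sharing_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """1 - (shared alleles / 2) averaged over jointly called markers.

    Per marker the shared-allele count between dosage genotypes d1, d2 is
    2 - |d1 - d2| (the size of the allele multiset intersection).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    both = (g1 != MISSING) & (g2 != MISSING)
    if not both.any():
        raise ValueError("no marker called in both genotypes")
    return float(np.abs(g1[both] - g2[both]).mean() / 2.0)


def allele_sharing_matrix(calls: np.ndarray) -> np.ndarray:
    """Full pairwise allele-sharing distance matrix (NaN-aware)."""
    g = np.asarray(calls, dtype=float)
    g[np.asarray(calls) == MISSING] = np.nan
    n = g.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(g[i + 1 :] - g[i][None, :]) / 2.0
        d = np.nanmean(diff, axis=1)
        if np.isnan(d).any():
            raise ValueError("a genotype pair shares no called marker")
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def cophenetic_matrix(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.linkage))

    def to_newick(self) -> str:
        """Serialize the merge tree to Newick.

        Branch lengths are half the merge-height differences (the UPGMA
        convention), so tip-to-tip path lengths equal cophenetic distances.
        """
        tree = hierarchy.to_tree(self.linkage)
        safe = [
            "".join("_" if ch in ":,();[] \t" else ch for ch in lab)
            for lab in self.labels
        ]

        def rec(node, parent_height):
            length = (parent_height - node.dist) / 2.0
            if node.is_leaf():
                return f"{safe[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        body = rec(tree, tree.dist)
        # root has no parent: strip its branch length
        return body.rsplit(":", 1)[0] + ";"


def cluster_genotypes(
    dist_matrix: np.ndarray, labels: list[str] | None = None, method: str = "ward"
) -> Dendrogram:
    """Deterministic agglomerative clustering of a genotype distance matrix."""
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("need a square distance matrix on >= 2 items")
    if labels is None:
        labels = [f"g{i}" for i in range(d.shape[0])]
    Z = hierarchy.linkage(squareform(d, checks=False), method=method)
    return Dendrogram(list(labels), Z)


@dataclass
class GapResult:
    k_hat: int
    gaps: np.ndarray  # per K = 1..K_max
    se: np.ndarray
    log_w: np.ndarray
    b_reference: int


def _within_dispersion(d: np.ndarray, assignment: np.ndarray) -> float:
    """Tibshirani W_K: sum over clusters of (pairwise distance sum)/(2 n_r)."""
    w = 0.0
    for c in np.unique(assignment):
        idx = np.flatnonzero(assignment == c)
        if idx.size > 1:
            w += d[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return w


def gap_statistic(
    calls: np.ndarray,
    k_max: int,
    b_reference: int = 100,
    seed: int | None = None,
    method: str = "ward",
) -> GapResult:
    """Choose the number of clusters by the gap statistic.

    Dispersion uses the allele-sharing distance and tree cuts of the
    agglomerative clustering.  The reference null redraws each marker's
    dosages independently from the observed dosage frequencies at that
    marker (preserving allele frequencies, destroying linkage and
    structure).  K_hat is the smallest K with
    gap(K) >= gap(K+1) - se(K+1).
    """
    calls = np.atleast_2d(np.asarray(calls))
    n = calls.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n <= k_max:
        raise ValueError("need more items than k_max")
    rng = np.random.default_rng(seed)

    def log_wk(c: np.ndarray) -> np.ndarray:
        d = allele_sharing_matrix(c)
        if not d.any():
            return np.full(k_max, -np.inf)
        dend = cluster_genotypes(d, method=method)
        out = np.empty(k_max)
        for k in range(1, k_max + 1):
            assignment = dend.cut(k) if k > 1 else np.ones(n, dtype=int)
            w = _within_dispersion(d, assignment)
            out[k - 1] = np.log(w) if w > 0 else -np.inf
        return out

    obs = log_wk(calls)
    if np.all(np.isinf(obs)):
        return GapResult(1, np.zeros(k_max), np.zeros(k_max), obs, b_reference)

    ref = np.empty((b_reference, k_max))
    for bi in range(b_reference):
        sim = np.empty_like(calls)
        for j in range(calls.shape[1]):
            col = calls[:, j]
            pool = col[col != MISSING]
            sim[:, j] = rng.choice(pool, size=n, replace=True) if pool.size else MISSING
        ref[bi] = log_wk(sim)

    gaps = ref.mean(axis=0) - obs
    sd = ref.std(axis=0, ddof=0)
    se = sd * np.sqrt(1.0 + 1.0 / b_reference)
    k_hat = k_max
    for k in range(1, k_max):
        if gaps[k - 1] >= gaps[k] - se[k]:
            k_hat = k
            break
    return GapResult(int(k_hat), gaps, se, obs, b_reference)


@dataclass
class GroupComparison:
    group_names: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    medians: tuple[float, float]
    u_statistic: float
    p_value: float
    degenerate: bool = False


def within_between_distributions(
    dist_matrix: np.ndarray, stand_ids: np.ndarray, exclude_zero_within: bool = False
) -> tuple[np.ndarray, np.ndarray, GroupComparison]:
    """Split pairwise distances into same-stand and different-stand sets.

    Returns the two distance lists and a rank-sum comparison (within vs
    between).  ``exclude_zero_within`` drops identical-genotype pairs from
    the within list before testing, mirroring the comparison of
    non-identical genotypes only.
    """
    d = np.asarray(dist_matrix, dtype=float)
    ids = np.asarray(stand_ids)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, 1)
    same = ids[iu] == ids[ju]
    within = d[iu[same], ju[same]]
    between = d[iu[~same], ju[~same]]
    w = within[within > 0] if exclude_zero_within else within
    if w.size and between.size and np.ptp(np.concatenate([w, between])) > 0:
        u, p = sps.mannwhitneyu(w, between, alternative="two-sided")
        degenerate = False
    else:
        u, p = np.nan, 1.0
        degenerate = True
    comp = GroupComparison(
        ("within", "between"),
        (int(w.size), int(between.size)),
        (float(w.mean()) if w.size else np.nan,
         float(between.mean()) if between.size else np.nan),
        (float(np.median(w)) if w.size else np.nan,
         float(np.median(between)) if between.size else np.nan),
        float(u) if u == u else np.nan,
        float(p),
        degenerate,
    )
    return within, between, comp


def compare_site_types(
    values_a: np.ndarray,
    values_b: np.ndarray,
    names: tuple[str, str] = ("rural", "urban"),
) -> GroupComparison:
    """Mann-Whitney rank-sum comparison of a per-stand statistic.

    Uses the exact null distribution for small groups without ties and the
    normal approximation otherwise (scipy's default policy).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupComparison(names, (a.size, b.size), (a.mean(), b.mean()),
                               (float(np.median(a)), float(np.median(b))),
                               np.nan, 1.0, True)
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        names, (int(a.size), int(b.size)),
        (float(a.mean()), float(b.mean())),
        (float(np.median(a)), float(np.median(b))),
        float(u), float(p), False,
    )


def nonredundant_mlg_table(
    table: GenotypeTable, mlg_table: MLGTable
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """One representative per MLG per (stand, year) for clustering input.

    Returns (calls, labels, stand_ids); labels are "stand|year|mlg"
    (newick-safe: no colons, commas or parentheses).
    """
    seen: dict[tuple, int] = {}
    rows, labels, stands = [], [], []
    for i, sid in enumerate(table.sample_ids):
        stand = table.meta["stand_id"].iloc[i]
        year = int(table.meta["year"].iloc[i])
        mlg = mlg_table.mlg_of[sid]
        key = (stand, year, mlg)
        if key in seen:
            continue
        seen[key] = i
        rows.append(mlg_table.canonical[mlg])
        labels.append(f"{stand}|{year}|{mlg}")
        stands.append(stand)
    return np.array(rows, dtype=np.int8), labels, np.array(stands)


def write_phylip_square(dist_matrix: np.ndarray, labels: list[str], path) -> None:
    """Write a distance matrix in PHYLIP square format."""
    d = np.asarray(dist_matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"{d.shape[0]}\n")
        for i, lab in enumerate(labels):
            row = " ".join(f"{x:.6f}" for x in d[i])
            fh.write(f"{lab[:10]:<10s} {row}\n")
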