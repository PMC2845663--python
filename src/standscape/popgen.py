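"""Diversity and inbreeding estimators for stand samples.

Implements gene diversity (expected heterozygosity with Nei's small-sample
correction), the inter-individual identity diversity 1-Q, Weir & Cockerham
variance-component F-statistics (F_IS, F_ST, F_IT), the effective
outcrossing transform OC = (1 - F_IS)/(1 + F_IS), the size-correcting
subsampling procedure (random subsamples of fixed size, re-iterated, with
locus-bootstrap confidence intervals), and matched-subsample F_ST between
two years of the same stand.

Conventions
-----------
Monomorphic loci contribute zero to genome-mean diversity but are excluded
from F-statistic ratios (they carry no information about heterozygote
deficit).  Multilocus F-statistics are ratios of variance-component sums
over loci, the standard small-sample-robust combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING

__all__ = [
    "DiversityResult",
    "FStats",
    "FstResult",
    "SubsampleConfig",
    "expected_heterozygosity",
    "one_minus_q",
    "observed_heterozygosity",
    "wc_components",
    "wc_f_statistics",
    "effective_outcrossing",
    "outcrossing_percent",
    "subsampled_stand_stats",
    "year_pair_fst",
]


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker (allele-b count, called-allele count) for a dosage matrix."""
    called = calls != MISSING
    nb = np.where(called, calls, 0).sum(axis=0).astype(float)
    n2 = 2.0 * called.sum(axis=0)
    return nb, n2


def expected_heterozygosity(calls: np.ndarray) -> np.ndarray:
    """Per-marker unbiased gene diversity (Nei & Chesser 1983).

    He = n/(n-1) * (1 - sum p_i^2 - Ho/(2n)) with n called individuals and
    Ho the observed heterozygote proportion.  Unlike the plain 2n/(2n-1)
    correction, this estimator stays unbiased under inbreeding, where the
    two alleles of an individual are not independent draws — essential for
    a selfing species.  Markers with fewer than two called individuals
    return NaN.
    """
    calls = np.atleast_2d(np.asarray(calls))
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    nb = np.where(called, calls, 0).sum(axis=0).astype(float)
    nhet = (calls == 1).sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = nb / (2.0 * n)
        ho = nhet / n
        he = (n / (n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2 - ho / (2.0 * n))
    he[n < 2] = np.nan
    return he


def observed_heterozygosity(calls: np.ndarray) -> np.ndarray:
    """Per-marker fraction of called individuals that are heterozygous."""
    calls = np.atleast_2d(np.asarray(calls))
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = (calls == 1).sum(axis=0) / n
    ho[n == 0] = np.nan
    return ho


def one_minus_q(calls: np.ndarray) -> np.ndarray:
    """Per-marker 1 - Q, with Q the inter-individual allele identity.

    Q is the probability that one allele drawn at random from each of two
    distinct individuals is identical, averaged over ordered pairs.  With
    per-individual allele frequencies f (0, 1/2 or 1 for a biallelic
    dosage), Q = (S^2 - sum_i f_i^2 summed over alleles) / (n (n - 1)).
    """
    calls = np.atleast_2d(np.asarray(calls))
    out = np.full(calls.shape[1], np.nan)
    for j in range(calls.shape[1]):
        col = calls[:, j]
        col = col[col != MISSING]
        n = col.size
        if n < 2:
            continue
        fb = col / 2.0
        q = 0.0
        for f in (fb, 1.0 - fb):
            q += f.sum() ** 2 - (f**2).sum()
        out[j] = 1.0 - q / (n * (n - 1))
    return out


# ---------------------------------------------------------------------------
# Weir & Cockerham variance components
# ---------------------------------------------------------------------------


def wc_components(
    calls: np.ndarray, stand_codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) of Weir & Cockerham (1984).

    ``stand_codes`` assigns each row (individual) to a population.  The
    among-population component ``a`` is NaN when fewer than two populations
    have data at a locus; ``b`` (among individuals within populations) and
    ``c`` (within individuals, = half the observed heterozygosity) are
    defined with one population as well, which is what single-stand F_IS
    uses.  Loci monomorphic over the populations get NaN components.
    """
    calls = np.asarray(calls)
    stand_codes = np.asarray(stand_codes)
    pops = np.unique(stand_codes)
    L = calls.shape[1]

    # per-pop, per-locus: sample size (individuals), allele-b freq, het freq
    n_i = np.zeros((len(pops), L))
    p_i = np.zeros((len(pops), L))
    h_i = np.zeros((len(pops), L))
    for k, pop in enumerate(pops):
        sub = calls[stand_codes == pop]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i[k] = np.where(called, sub, 0).sum(axis=0) / (2.0 * n)
            h_i[k] = (sub == 1).sum(axis=0) / n
        n_i[k] = n

    a = np.full(L, np.nan)
    b = np.full(L, np.nan)
    c = np.full(L, np.nan)
    for j in range(L):
        use = n_i[:, j] > 0
        r = int(use.sum())
        if r == 0:
            continue
        n = n_i[use, j]
        p = p_i[use, j]
        h = h_i[use, j]
        nbar = n.mean()
        ntot = n.sum()
        pbar = (n * p).sum() / ntot
        hbar = (n * h).sum() / ntot
        if pbar <= 0.0 or pbar >= 1.0:
            continue  # monomorphic: no information
        if r >= 2:
            s2 = (n * (p - pbar) ** 2).sum() / ((r - 1.0) * nbar)
            nc = (ntot - (n**2).sum() / ntot) / (r - 1.0)
            a[j] = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1.0))
                * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
            )
            b[j] = (nbar / (nbar - 1.0)) * (
                pbar * (1.0 - pbar)
                - s2 * (r - 1.0) / r
                - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
            )
        else:
            if nbar < 2:
                continue
            a[j] = np.nan
            b[j] = (nbar / (nbar - 1.0)) * (
                pbar * (1.0 - pbar) - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
            )
        c[j] = hbar / 2.0
    return a, b, c


@dataclass
class FStats:
    """Multilocus F-statistics as ratios of summed variance components."""

    f_is: float
    f_st: float
    f_it: float
    n_loci: int  # informative (polymorphic) loci used
    a: np.ndarray = field(repr=False, default=None)
    b: np.ndarray = field(repr=False, default=None)
    c: np.ndarray = field(repr=False, default=None)


def wc_f_statistics(calls: np.ndarray, stand_codes: np.ndarray | None = None) -> FStats:
    """Multilocus Weir & Cockerham F_IS / F_ST / F_IT.

    With a single population (or ``stand_codes`` omitted) only F_IS is
    defined.  All loci monomorphic yields NaN statistics.
    """
    calls = np.asarray(calls)
    if stand_codes is None:
        stand_codes = np.zeros(calls.shape[0], dtype=int)
    a, b, c = wc_components(calls, stand_codes)
    use_is = ~np.isnan(b) & ~np.isnan(c)
    n_loci = int(use_is.sum())
    if n_loci == 0:
        return FStats(np.nan, np.nan, np.nan, 0, a, b, c)
    bc = b[use_is].sum() + c[use_is].sum()
    f_is = 1.0 - c[use_is].sum() / bc if bc != 0 else np.nan
    use_st = use_is & ~np.isnan(a)
    if use_st.any():
        abc = a[use_st].sum() + b[use_st].sum() + c[use_st].sum()
        f_st = a[use_st].sum() / abc if abc != 0 else np.nan
        f_it = 1.0 - c[use_st].sum() / abc if abc != 0 else np.nan
    else:
        f_st = f_it = np.nan
    return FStats(float(f_is), float(f_st), float(f_it), n_loci, a, b, c)


# ---------------------------------------------------------------------------
# effective outcrossing
# ---------------------------------------------------------------------------


def effective_outcrossing(f_is: float) -> float:
    """Effective outcrossing rate implied by F_IS at inbreeding equilibrium.

    OC = 1 - 2 F_IS/(1 + F_IS) = (1 - F_IS)/(1 + F_IS).  At equilibrium
    under partial selfing with unrelated outcross partners this inverts
    F = (1 - t)/(1 + t); it measures the rate of generation of
    heterozygotes, not necessarily the true mating rate (spatial structure
    and mating among relatives inflate F_IS — the Wahlund effect).
    """
    if f_is == -1.0:
        raise ValueError("effective outcrossing is undefined at F_IS = -1")
    return (1.0 - f_is) / (1.0 + f_is)


def outcrossing_percent(f_is: float, decimals: int = 1) -> float:
    """Effective outcrossing as a percentage rounded for reporting."""
    return round(100.0 * effective_outcrossing(f_is), decimals)


# ---------------------------------------------------------------------------
# size-corrected subsampling
# ---------------------------------------------------------------------------


@dataclass
class SubsampleConfig:
    subsample_size: int = 10
    n_reps: int = 100
    bootstrap_reps: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if self.subsample_size < 2:
            raise ValueError("subsample_size must be >= 2")
        if self.n_reps < 1 or self.bootstrap_reps < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass
class DiversityResult:
    stand_id: str
    n_used: int
    he: float
    he_ci: tuple[float, float]
    one_minus_q: float
    ho: float
    f_is: float
    f_is_ci: tuple[float, float]
    oc: float  # effective outcrossing fraction
    per_marker_he: np.ndarray = field(repr=False, default=None)


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return (np.nan, np.nan)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def subsampled_stand_stats(
    calls: np.ndarray,
    stand_id: str = "",
    config: SubsampleConfig | None = None,
) -> DiversityResult:
    """Size-corrected stand diversity by repeated fixed-size subsampling.

    Draws ``subsample_size`` individuals without replacement, computes
    per-marker He and Weir-Cockerham components, repeats ``n_reps`` times
    and averages per marker before averaging across the genome.  The stand
    F_IS is the ratio of rep-averaged component sums.  95% confidence
    intervals come from bootstrapping loci (resampling markers with
    replacement from the rep-averaged per-marker values).

    Stands smaller than the subsample size are the caller's responsibility
    to exclude (mirrors the n >= 10 analysis filter); a stand of exactly
    the subsample size reduces to the direct estimate.
    """
    if config is None:
        config = SubsampleConfig()
    calls = np.atleast_2d(np.asarray(calls))
    n, L = calls.shape
    if n < config.subsample_size:
        raise ValueError(
            f"stand has {n} < subsample_size={config.subsample_size} individuals"
        )
    rng = np.random.default_rng(config.seed)
    reps = config.n_reps if n > config.subsample_size else 1

    he_sum = np.zeros(L)
    he_cnt = np.zeros(L)
    b_sum = np.zeros(L)
    c_sum = np.zeros(L)
    bc_cnt = np.zeros(L)
    ho_sum = np.zeros(L)
    q_like = np.zeros(L)
    for _ in range(reps):
        idx = (
            np.arange(n)
            if n == config.subsample_size
            else rng.choice(n, size=config.subsample_size, replace=False)
        )
        sub = calls[idx]
        he = expected_heterozygosity(sub)
        ok = ~np.isnan(he)
        he_sum[ok] += he[ok]
        he_cnt[ok] += 1
        ho = observed_heterozygosity(sub)
        ho_sum[~np.isnan(ho)] += ho[~np.isnan(ho)]
        _, b, c = wc_components(sub, np.zeros(len(idx), dtype=int))
        okbc = ~np.isnan(b) & ~np.isnan(c)
        b_sum[okbc] += b[okbc]
        c_sum[okbc] += c[okbc]
        bc_cnt[okbc] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        he_marker = np.where(he_cnt > 0, he_sum / np.maximum(he_cnt, 1), 0.0)
        # markers never estimable (e.g. monomorphic subsample) count as 0
        he_marker[he_cnt == 0] = 0.0
        b_marker = np.where(bc_cnt > 0, b_sum / np.maximum(bc_cnt, 1), np.nan)
        c_marker = np.where(bc_cnt > 0, c_sum / np.maximum(bc_cnt, 1), np.nan)
        ho_marker = ho_sum / reps

    he_mean = float(he_marker.mean())
    q_marker = one_minus_q(calls)
    omq = float(np.nan_to_num(q_marker, nan=0.0).mean())
    ho_mean = float(ho_marker.mean())

    inform = ~np.isnan(b_marker)
    if inform.any() and (b_marker[inform].sum() + c_marker[inform].sum()) != 0:
        f_is = 1.0 - c_marker[inform].sum() / (
            b_marker[inform].sum() + c_marker[inform].sum()
        )
    else:
        f_is = np.nan

    # locus bootstrap (Weir 1996): resample markers with replacement
    boot_he = np.empty(config.bootstrap_reps)
    boot_fis = np.full(config.bootstrap_reps, np.nan)
    inf_idx = np.flatnonzero(inform)
    for r in range(config.bootstrap_reps):
        pick = rng.integers(0, L, size=L)
        boot_he[r] = he_marker[pick].mean()
        pick_inf = pick[np.isin(pick, inf_idx)]
        if pick_inf.size:
            bc = b_marker[pick_inf].sum() + c_marker[pick_inf].sum()
            if bc != 0:
                boot_fis[r] = 1.0 - c_marker[pick_inf].sum() / bc

    oc = effective_outcrossing(f_is) if not np.isnan(f_is) and f_is != -1 else np.nan
    return DiversityResult(
        stand_id=stand_id,
        n_used=config.subsample_size,
        he=he_mean,
        he_ci=_percentile_ci(boot_he),
        one_minus_q=omq,
        ho=ho_mean,
        f_is=float(f_is),
        f_is_ci=_percentile_ci(boot_fis),
        oc=float(oc) if oc == oc else np.nan,
        per_marker_he=he_marker,
    )


# ---------------------------------------------------------------------------
# year-to-year differentiation
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    stand_id: str
    theta: float
    ci: tuple[float, float]
    n_small: int
    n_large: int
    degenerate: bool = False


def year_pair_fst(
    calls_year1: np.ndarray,
    calls_year2: np.ndarray,
    stand_id: str = "",
    n_reps: int = 100,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> FstResult:
    """Matched-subsample F_ST between two samples of the same stand.

    The larger sample is repeatedly subsampled down to the size of the
    smaller one; theta (Weir-Cockerham) is computed for each subsample
    against the smaller sample and averaged over replicates.  Confidence
    intervals bootstrap loci on the replicate-averaged components.
    """
    rng = np.random.default_rng(seed)
    g1 = np.atleast_2d(np.asarray(calls_year1))
    g2 = np.atleast_2d(np.asarray(calls_year2))
    if g1.shape[1] != g2.shape[1]:
        raise ValueError("year samples must share the marker panel")
    small, large = (g1, g2) if g1.shape[0] <= g2.shape[0] else (g2, g1)
    n_small = small.shape[0]
    L = g1.shape[1]
    reps = n_reps if large.shape[0] > n_small else 1

    a_sum = np.zeros(L)
    b_sum = np.zeros(L)
    c_sum = np.zeros(L)
    cnt = np.zeros(L)
    for _ in range(reps):
        idx = (
            np.arange(large.shape[0])
            if large.shape[0] == n_small
            else rng.choice(large.shape[0], size=n_small, replace=False)
        )
        pooled = np.vstack([small, large[idx]])
        codes = np.repeat([0, 1], [n_small, n_small])
        a, b, c = wc_components(pooled, codes)
        ok = ~np.isnan(a)
        a_sum[ok] += a[ok]
        b_sum[ok] += b[ok]
        c_sum[ok] += c[ok]
        cnt[ok] += 1

    inform = cnt > 0
    if not inform.any():
        return FstResult(stand_id, 0.0, (0.0, 0.0), n_small, large.shape[0], True)
    with np.errstate(invalid="ignore"):
        a_m = a_sum[inform] / cnt[inform]
        b_m = b_sum[inform] / cnt[inform]
        c_m = c_sum[inform] / cnt[inform]
    denom = (a_m + b_m + c_m).sum()
    theta = a_m.sum() / denom if denom != 0 else np.nan

    boot = np.full(bootstrap_reps, np.nan)
    k = inform.sum()
    for r in range(bootstrap_reps):
        pick = rng.integers(0, k, size=k)
        d = (a_m[pick] + b_m[pick] + c_m[pick]).sum()
        if d != 0:
            boot[r] = a_m[pick].sum() / d
    return FstResult(
        stand_id, float(theta), _percentile_ci(boot), n_small, large.shape[0], False
    )
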