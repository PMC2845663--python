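"""Independent brute-force oracles used to validate the implementation.

Each oracle is coded from first principles (definitions, enumeration, or
ANOVA sums of squares) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics via the gametic ANOVA
# ---------------------------------------------------------------------------


def wc_anova_components(calls, pops):
    """Per-locus variance components from the nested gametic ANOVA.

    Alleles (2 per individual) are nested in individuals nested in
    populations.  For each locus, with y the allele-b indicator:
    sigma2_G = MS(within individuals); sigma2_I = (MS(individuals) -
    MS(within))/2; sigma2_P = (MS(pops) - MS(individuals))/(2 nc).
    These equal Weir & Cockerham's c, b and a estimators.
    """
    calls = np.asarray(calls)
    pops = np.asarray(pops)
    L = calls.shape[1]
    a_out, b_out, c_out = [], [], []
    pair_of = {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (1.0, 1.0)}
    for j in range(L):
        ys = []  # per pop: list of (allele1, allele2) indicator pairs
        for p in sorted(set(pops.tolist())):
            rows = calls[pops == p, j]
            rows = rows[rows != MISSING]
            if rows.size:
                ys.append([pair_of[int(d)] for d in rows])
        r = len(ys)
        n_i = np.array([len(g) for g in ys], dtype=float)
        if r == 0 or (n_i < 2).all() and r == 1:
            a_out.append(np.nan); b_out.append(np.nan); c_out.append(np.nan)
            continue
        ntot = n_i.sum()
        ybar_i = np.array([np.mean([y for pair in g for y in pair]) for g in ys])
        ybar = sum(n_i[i] * ybar_i[i] for i in range(r)) / ntot
        if ybar <= 0 or ybar >= 1:
            a_out.append(np.nan); b_out.append(np.nan); c_out.append(np.nan)
            continue
        ss_g = sum(
            (y - (pair[0] + pair[1]) / 2.0) ** 2
            for g in ys for pair in g for y in pair
        )
        ss_i = sum(
            2.0 * ((pair[0] + pair[1]) / 2.0 - ybar_i[i]) ** 2
            for i, g in enumerate(ys) for pair in g
        )
        ms_g = ss_g / ntot
        ms_i = ss_i / (ntot - r)
        sigma_g = ms_g
        sigma_i = (ms_i - ms_g) / 2.0
        if r >= 2:
            ss_p = sum(2.0 * n_i[i] * (ybar_i[i] - ybar) ** 2 for i in range(r))
            ms_p = ss_p / (r - 1)
            nc = (ntot - (n_i**2).sum() / ntot) / (r - 1)
            sigma_p = (ms_p - ms_i) / (2.0 * nc)
        else:
            sigma_p = np.nan
        a_out.append(sigma_p)
        b_out.append(sigma_i)
        c_out.append(sigma_g)
    return np.array(a_out), np.array(b_out), np.array(c_out)


def wc_anova_fstats(calls, pops):
    a, b, c = wc_anova_components(calls, pops)
    ok = ~np.isnan(b) & ~np.isnan(c)
    f_is = 1.0 - c[ok].sum() / (b[ok].sum() + c[ok].sum()) if ok.any() else np.nan
    ok_st = ok & ~np.isnan(a)
    if ok_st.any():
        tot = a[ok_st].sum() + b[ok_st].sum() + c[ok_st].sum()
        f_st = a[ok_st].sum() / tot
        f_it = 1.0 - c[ok_st].sum() / tot
    else:
        f_st = f_it = np.nan
    return f_is, f_st, f_it


# ---------------------------------------------------------------------------
# MLG partition by exhaustive pairwise compatibility closure
# ---------------------------------------------------------------------------


def mlg_partition_bruteforce(calls, min_call_rate=0.95):
    """Transitive closure of pairwise wildcard compatibility, O(n^2 L)."""
    calls = np.asarray(calls)
    n, L = calls.shape
    eligible = [(calls[i] != MISSING).sum() >= min_call_rate * L for i in range(n)]
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                adj[i][j] = True
                continue
            if not (eligible[i] and eligible[j]):
                continue
            ok = True
            for k in range(L):
                if calls[i, k] != MISSING and calls[j, k] != MISSING and calls[i, k] != calls[j, k]:
                    ok = False
                    break
            adj[i][j] = ok
    # transitive closure by repeated sweeps
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if adj[i][j] and labels[j] != labels[i]:
                    lo = min(labels[i], labels[j])
                    hi = max(labels[i], labels[j])
                    for k in range(n):
                        if labels[k] == hi:
                            labels[k] = lo
                    changed = True
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return sorted(tuple(sorted(v)) for v in groups.values())


# ---------------------------------------------------------------------------
# exhaustive minimal-breakpoint painting
# ---------------------------------------------------------------------------


def min_breakpoints_exhaustive(genotype, founder_a, founder_b, chroms):
    """Minimum label switches over all founder-origin paintings consistent
    with the genotype, enumerated exhaustively (use only for <= ~12
    differentiating markers)."""
    g = np.asarray(genotype)
    fa = np.asarray(founder_a)
    fb = np.asarray(founder_b)
    diff_idx = [
        k
        for k in range(g.size)
        if fa[k] != MISSING and fb[k] != MISSING and fa[k] != fb[k] and g[k] != MISSING
    ]
    options = []
    for k in diff_idx:
        opts = []
        if g[k] == fa[k]:
            opts.append(0)
        if g[k] == fb[k]:
            opts.append(1)
        if not opts:
            continue  # unexplained marker: no label
        options.append((k, opts))
    if not options:
        return 0
    best = None
    for combo in itertools.product(*[o for _, o in options]):
        switches = 0
        for (k1, _), l1, (k2, _), l2 in zip(
            options, combo, options[1:], combo[1:]
        ):
            if chroms[k1] == chroms[k2] and l1 != l2:
                switches += 1
        best = switches if best is None else min(best, switches)
    return best


# ---------------------------------------------------------------------------
# plain-definition Moran's I for one variable
# ---------------------------------------------------------------------------


def morans_i_direct(values, weight_matrix):
    """Moran's I from its textbook definition for one variable."""
    y = np.asarray(values, dtype=float)
    w = np.asarray(weight_matrix, dtype=float)
    n = y.size
    z = y - y.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n * num / (w.sum() * (z**2).sum())
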