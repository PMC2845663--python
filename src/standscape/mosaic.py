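"""Genome-scan for outcrossing and recombination footprints.

In a predominantly selfing plant, an outcrossing event followed by selfing
leaves characteristic marks in dense SNP data: pairwise comparisons of
genotypes show mosaic blocks of alternating identity and divergence along
chromosomes; recent outcrosses carry extended stretches of linked
heterozygous markers; a first-generation (F1) outcross is heterozygous at
every marker differentiating its two homozygous parents; and stands founded
by a single ancient outcross consist of natural recombinant inbred lines
(RILs) — homozygous mosaics of just two founder genomes.

This module automates those scans.  Missing calls are neutral throughout:
they never break a run and never count toward identity or divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import MISSING, MarkerMap

__all__ = [
    "MarkerStatus",
    "PairwiseProfile",
    "Block",
    "HetStretch",
    "F1Call",
    "RILReconstruction",
    "pairwise_profile",
    "segment_blocks",
    "detect_het_stretches",
    "assign_f1_parents",
    "reconstruct_ril",
]


class MarkerStatus(str, Enum):
    IDENTICAL = "identical"
    DIVERGENT = "divergent"
    HET_INVOLVED = "het_involved"
    MISSING = "missing"


@dataclass
class PairwiseProfile:
    sample_a: str
    sample_b: str
    status: np.ndarray  # int8 codes, see _STATUS_CODES
    marker_map: MarkerMap

    def status_labels(self) -> list[str]:
        rev = {v: k.value for k, v in _STATUS_CODES.items()}
        return [rev[int(s)] for s in self.status]


_STATUS_CODES = {
    MarkerStatus.IDENTICAL: 0,
    MarkerStatus.DIVERGENT: 1,
    MarkerStatus.HET_INVOLVED: 2,
    MarkerStatus.MISSING: 3,
}


def pairwise_profile(
    g1: np.ndarray, g2: np.ndarray, marker_map: MarkerMap,
    sample_a: str = "a", sample_b: str = "b",
) -> PairwiseProfile:
    """Per-marker identity status between two genotypes.

    identical: equal homozygous dosages; divergent: opposite homozygotes;
    het_involved: either call heterozygous; missing: either call missing.
    Symmetric in the pair.
    """
    g1 = np.asarray(g1, dtype=np.int8)
    g2 = np.asarray(g2, dtype=np.int8)
    if g1.shape != g2.shape or g1.size != len(marker_map):
        raise ValueError("genotypes must match the marker map")
    status = np.empty(g1.size, dtype=np.int8)
    miss = (g1 == MISSING) | (g2 == MISSING)
    het = (g1 == 1) | (g2 == 1)
    ident = g1 == g2
    status[:] = _STATUS_CODES[MarkerStatus.DIVERGENT]
    status[ident] = _STATUS_CODES[MarkerStatus.IDENTICAL]
    status[het] = _STATUS_CODES[MarkerStatus.HET_INVOLVED]
    status[miss] = _STATUS_CODES[MarkerStatus.MISSING]
    return PairwiseProfile(sample_a, sample_b, status, marker_map)


@dataclass
class Block:
    chromosome: int
    first_index: int  # global marker index, 0-based inclusive
    last_index: int
    state: str  # "identity" | "divergence"
    n_markers: int  # informative markers in the block
    bp_start: int
    bp_end: int
    flagged: bool = False  # chromosome too short to satisfy min_run


def segment_blocks(profile: PairwiseProfile, min_run: int = 5) -> list[Block]:
    """Segment a pairwise profile into identity/divergence mosaic blocks.

    Heterozygous and missing markers are neutral.  Runs of informative
    markers shorter than ``min_run`` are absorbed into a flanking run
    (shortest run first, ties leftmost; absorbed into the longer neighbor,
    left on ties), which makes the output deterministic.  With
    ``min_run=1`` the segmentation is lossless.  Blocks tile each
    chromosome: neutral markers between runs attach to the preceding
    block.
    """
    code_i = _STATUS_CODES[MarkerStatus.IDENTICAL]
    code_d = _STATUS_CODES[MarkerStatus.DIVERGENT]
    blocks: list[Block] = []
    mm = profile.marker_map
    for chrom, sl in mm.chromosome_slices().items():
        status = profile.status[sl]
        info_local = np.flatnonzero((status == code_i) | (status == code_d))
        if info_local.size == 0:
            continue
        states = [int(status[i] == code_d) for i in info_local]  # 0=identity 1=div
        # run-length encoding over informative markers
        runs: list[list[int]] = []  # [state, count]
        for s in states:
            if runs and runs[-1][0] == s:
                runs[-1][1] += 1
            else:
                runs.append([s, 1])
        flagged = info_local.size < min_run
        # absorb short runs into a flanking run, shortest (then leftmost) first
        while len(runs) > 1:
            lens = [r[1] for r in runs]
            k = int(np.argmin(lens))
            if lens[k] >= min_run:
                break
            left = runs[k - 1][1] if k > 0 else -1
            right = runs[k + 1][1] if k < len(runs) - 1 else -1
            target = k - 1 if left >= right else k + 1
            runs[target][1] += runs[k][1]
            del runs[k]
            # merge newly adjacent equal-state runs
            merged: list[list[int]] = []
            for r in runs:
                if merged and merged[-1][0] == r[0]:
                    merged[-1][1] += r[1]
                else:
                    merged.append(list(r))
            runs = merged
        # expand runs back to marker index ranges tiling the chromosome
        pos = 0
        for b, (state, count) in enumerate(runs):
            last_info = info_local[pos + count - 1]
            start_local = 0 if b == 0 else (blocks[-1].last_index - sl.start + 1)
            end_local = (len(status) - 1) if b == len(runs) - 1 else int(last_info)
            blocks.append(
                Block(
                    chromosome=chrom,
                    first_index=sl.start + int(start_local),
                    last_index=sl.start + int(end_local),
                    state="divergence" if state else "identity",
                    n_markers=int(count),
                    bp_start=int(mm.positions[sl.start + int(start_local)]),
                    bp_end=int(mm.positions[sl.start + int(end_local)]),
                    flagged=flagged,
                )
            )
            pos += count
    return blocks


@dataclass
class HetStretch:
    sample_id: str
    chromosome: int
    first_index: int  # global marker index of first heterozygous call
    last_index: int
    n_het: int


def detect_het_stretches(
    calls: np.ndarray,
    marker_map: MarkerMap,
    sample_id: str = "",
    min_run: int = 3,
    max_interrupt: int = 1,
) -> tuple[list[HetStretch], float]:
    """Find runs of linked heterozygous markers; report genome het fraction.

    A stretch is a maximal run of dosage-1 calls on one chromosome
    containing at least ``min_run`` heterozygous markers, tolerating at
    most ``max_interrupt`` called homozygous markers inside the run;
    missing calls are neutral.  Stretches begin and end at heterozygous
    markers.  Returns the stretches and the genome-wide fraction of called
    markers that are heterozygous.
    """
    calls = np.asarray(calls, dtype=np.int8)
    stretches: list[HetStretch] = []
    for chrom, sl in marker_map.chromosome_slices().items():
        sub = calls[sl]
        het_pos = np.flatnonzero(sub == 1)
        if het_pos.size == 0:
            continue
        # greedy scan: extend a run while interruptions stay within budget
        start = 0
        while start < het_pos.size:
            end = start
            interrupts = 0
            while end + 1 < het_pos.size:
                between = sub[het_pos[end] + 1 : het_pos[end + 1]]
                n_hom = int(np.sum((between != MISSING) & (between != 1)))
                if interrupts + n_hom > max_interrupt:
                    break
                interrupts += n_hom
                end += 1
            n_het = end - start + 1
            if n_het >= min_run:
                stretches.append(
                    HetStretch(
                        sample_id,
                        chrom,
                        sl.start + int(het_pos[start]),
                        sl.start + int(het_pos[end]),
                        n_het,
                    )
                )
            start = end + 1
    called = calls != MISSING
    het_fraction = float((calls == 1).sum() / max(called.sum(), 1))
    return stretches, het_fraction


# ---------------------------------------------------------------------------
# F1 parent assignment
# ---------------------------------------------------------------------------


@dataclass
class F1Call:
    child_id: str
    parent_a: str | None
    parent_b: str | None
    n_differentiating: int
    fraction_heterozygous: float
    verdict: str  # "first_generation" | "later_generation_or_recombinant" | "none"


def _is_homozygous(g: np.ndarray) -> bool:
    return not np.any(g == 1)


def assign_f1_parents(
    child: np.ndarray,
    candidate_mlgs: dict[str, np.ndarray],
    child_id: str = "",
    threshold: float = 1.0,
) -> F1Call:
    """Find the homozygous parent pair best explaining a putative outcross.

    For every unordered pair of homozygous candidate MLGs differing at at
    least one marker, score the fraction of differentiating markers (both
    parents called, child called) at which the child is heterozygous.  The
    best pair maximizes that fraction, then the number of differentiating
    markers, then lexicographic MLG ids.  The verdict is
    ``first_generation`` when the fraction reaches ``threshold`` (default:
    heterozygous at every differentiating marker) and the child matches the
    shared homozygous state at non-differentiating markers; a positive but
    sub-threshold fraction (or a non-differentiating mismatch) is a
    later-generation outcross descendant or recombinant; a zero fraction
    (e.g. the child is simply one of the candidates' selfed offspring)
    gives ``none``.
    """
    child = np.asarray(child, dtype=np.int8)
    homs = {k: np.asarray(v, dtype=np.int8) for k, v in candidate_mlgs.items()
            if _is_homozygous(np.asarray(v))}
    best: tuple[float, int, str, str] | None = None
    ids = sorted(homs)
    child_called = child != MISSING
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = homs[ids[i]], homs[ids[j]]
            both = (a != MISSING) & (b != MISSING)
            diff = both & (a != b)
            use = diff & child_called
            n_diff = int(use.sum())
            if n_diff == 0:
                continue
            frac = float((child[use] == 1).sum() / n_diff)
            # pairs visited in lexicographic order: strict > keeps the
            # lexicographically smallest pair on ties
            if best is None or (frac, n_diff) > (best[0], best[1]):
                best = (frac, n_diff, ids[i], ids[j])
    if best is None or best[0] == 0.0:
        return F1Call(child_id, None, None, 0 if best is None else best[1],
                      0.0, "none")
    frac, n_diff, pa, pb = best
    a, b = homs[pa], homs[pb]
    shared = (a != MISSING) & (b != MISSING) & (a == b) & child_called
    matches_shared = bool(np.all(child[shared] == a[shared]))
    if frac >= threshold and matches_shared:
        verdict = "first_generation"
    else:
        verdict = "later_generation_or_recombinant"
    return F1Call(child_id, pa, pb, n_diff, frac, verdict)


# ---------------------------------------------------------------------------
# natural recombinant inbred lines
# ---------------------------------------------------------------------------


@dataclass
class RILReconstruction:
    stand_id: str
    founder_a: str
    founder_b: str
    # per individual: founder-origin label per marker (0=A, 1=B, -1 undefined)
    paintings: dict[str, np.ndarray]
    breakpoints: dict[str, int]
    unexplained: dict[str, int]
    total_unexplained: int
    total_breakpoints: int


def _paint_against(
    g: np.ndarray, fa: np.ndarray, fb: np.ndarray
) -> tuple[np.ndarray, int]:
    """Founder-origin labels at differentiating markers; count unexplained.

    A marker is unexplained when the individual is called, both founders
    are called, and the individual's genotype matches neither founder —
    including markers where the founders agree (otherwise a recombinant
    line could itself pose as a founder at zero cost).
    """
    both = (fa != MISSING) & (fb != MISSING) & (g != MISSING)
    diff = both & (fa != fb)
    paint = np.full(g.size, -1, dtype=np.int8)
    unexplained = int(np.sum(both & (g != fa) & (g != fb)))
    idx = np.flatnonzero(diff)
    for k in idx:
        if g[k] == fa[k]:
            paint[k] = 0
        elif g[k] == fb[k]:
            paint[k] = 1
    return paint, unexplained


def _count_breakpoints(paint: np.ndarray, marker_map: MarkerMap) -> int:
    """State switches of the painting along marker order, per chromosome."""
    total = 0
    for _, sl in marker_map.chromosome_slices().items():
        labels = paint[sl]
        labels = labels[labels >= 0]
        if labels.size > 1:
            total += int((labels[1:] != labels[:-1]).sum())
    return total


def reconstruct_ril(
    stand_mlgs: dict[str, np.ndarray],
    marker_map: MarkerMap,
    stand_id: str = "",
) -> RILReconstruction:
    """Explain a stand's homozygous MLGs as mosaics of two founders.

    Searches all pairs of distinct homozygous MLGs as candidate founders;
    every individual is painted by founder origin at the markers where the
    founders differ, breakpoints are counted as label switches along each
    chromosome, and markers matching neither founder are unexplained.  The
    best founder pair minimizes total unexplained markers, then total
    breakpoints, then lexicographic ids.
    """
    homs = {k: np.asarray(v, dtype=np.int8) for k, v in stand_mlgs.items()
            if _is_homozygous(np.asarray(v))}
    ids = sorted(homs)
    pairs = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if np.any(
            (homs[ids[i]] != homs[ids[j]])
            & (homs[ids[i]] != MISSING)
            & (homs[ids[j]] != MISSING)
        )
    ]
    if not pairs:
        raise ValueError("no pair of distinct homozygous MLGs to reconstruct from")
    best = None
    for pa, pb in pairs:
        fa, fb = homs[pa], homs[pb]
        paintings: dict[str, np.ndarray] = {}
        bps: dict[str, int] = {}
        unexp: dict[str, int] = {}
        for mid, g in stand_mlgs.items():
            paint, u = _paint_against(np.asarray(g, dtype=np.int8), fa, fb)
            paintings[mid] = paint
            bps[mid] = _count_breakpoints(paint, marker_map)
            unexp[mid] = u
        tot_u = sum(unexp.values())
        tot_b = sum(bps.values())
        key = (tot_u, tot_b, pa, pb)
        if best is None or key < best[0]:
            best = (key, RILReconstruction(stand_id, pa, pb, paintings, bps,
                                           unexp, tot_u, tot_b))
    return best[1]
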