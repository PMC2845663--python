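"""Mosaic blocks, heterozygous stretches, F1 calls, RIL reconstruction."""

import numpy as np
import pytest

from standscape import mosaic
from standscape.core import MISSING
from standscape.simulate import make_ril_stand

from conftest import make_map
from oracles import min_breakpoints_exhaustive


def profile_from_statuses(statuses, marker_map):
    """Build a PairwiseProfile with a prescribed status sequence."""
    code = {
        "I": 0, "D": 1, "H": 2, "M": 3,
    }
    arr = np.array([code[s] for s in statuses], dtype=np.int8)
    return mosaic.PairwiseProfile("a", "b", arr, marker_map)


class TestPairwiseProfile:
    def test_identical_and_divergent_and_het(self):
        mm = make_map(4, n_chrom=1)
        g1 = np.array([0, 0, 1, 0], dtype=np.int8)
        g2 = np.array([0, 2, 0, MISSING], dtype=np.int8)
        prof = mosaic.pairwise_profile(g1, g2, mm)
        assert prof.status_labels() == [
            "identical", "divergent", "het_involved", "missing",
        ]

    def test_symmetry(self):
        mm = make_map(5, n_chrom=1)
        rng = np.random.default_rng(0)
        g1 = rng.integers(0, 3, 5).astype(np.int8)
        g2 = rng.integers(0, 3, 5).astype(np.int8)
        p1 = mosaic.pairwise_profile(g1, g2, mm)
        p2 = mosaic.pairwise_profile(g2, g1, mm)
        np.testing.assert_array_equal(p1.status, p2.status)


class TestSegmentBlocks:
    def test_uniform_identity_gives_one_block_per_chromosome(self):
        mm = make_map(10, n_chrom=2)
        prof = profile_from_statuses("I" * 10, mm)
        blocks = mosaic.segment_blocks(prof)
        assert len(blocks) == 2
        assert all(b.state == "identity" for b in blocks)

    def test_three_constructed_blocks_with_boundaries(self):
        mm = make_map(30, n_chrom=1)
        prof = profile_from_statuses("I" * 10 + "D" * 10 + "I" * 10, mm)
        blocks = mosaic.segment_blocks(prof, min_run=5)
        assert [(b.first_index, b.last_index, b.state) for b in blocks] == [
            (0, 9, "identity"), (10, 19, "divergence"), (20, 29, "identity"),
        ]

    def test_min_run_one_is_lossless(self):
        mm = make_map(12, n_chrom=1)
        statuses = "IDDIIDIDDDII"
        prof = profile_from_statuses(statuses, mm)
        blocks = mosaic.segment_blocks(prof, min_run=1)
        rebuilt = []
        for b in blocks:
            rebuilt.extend(
                ("I" if b.state == "identity" else "D") * (b.last_index - b.first_index + 1)
            )
        assert "".join(rebuilt) == statuses

    def test_short_runs_absorbed_into_flank(self):
        mm = make_map(21, n_chrom=1)
        prof = profile_from_statuses("I" * 10 + "D" + "I" * 10, mm)
        blocks = mosaic.segment_blocks(prof, min_run=5)
        assert len(blocks) == 1
        assert blocks[0].state == "identity"

    def test_neutral_markers_do_not_break_blocks(self):
        mm = make_map(20, n_chrom=1)
        prof = profile_from_statuses("I" * 8 + "HM" + "I" * 10, mm)
        blocks = mosaic.segment_blocks(prof, min_run=5)
        assert len(blocks) == 1
        assert (blocks[0].first_index, blocks[0].last_index) == (0, 19)

    def test_blocks_tile_each_chromosome(self):
        mm = make_map(40, n_chrom=2)
        rng = np.random.default_rng(1)
        statuses = "".join(rng.choice(list("IDHM"), 40))
        blocks = mosaic.segment_blocks(profile_from_statuses(statuses, mm), min_run=3)
        for chrom, sl in mm.chromosome_slices().items():
            bl = [b for b in blocks if b.chromosome == chrom]
            if not bl:
                continue
            assert bl[0].first_index == sl.start
            assert bl[-1].last_index == sl.stop - 1
            for x, y in zip(bl, bl[1:]):
                assert y.first_index == x.last_index + 1
                assert y.state != x.state

    def test_simulated_recombinant_boundaries_near_true_crossovers(self):
        table, truth = make_ril_stand(n_lines=6, n_markers=80, n_meioses=1, seed=5)
        mm = truth["marker_map"]
        fa = truth["founders"]["founderA"]
        fb = truth["founders"]["founderB"]
        for i, sid in enumerate(table.sample_ids):
            if not sid.startswith("ril"):
                continue
            prof = mosaic.pairwise_profile(table.calls[i], fa, mm)
            blocks = mosaic.segment_blocks(prof, min_run=1)
            paint = truth["paintings"][sid]
            # each block boundary must coincide with a change in true origin
            # at some differentiating marker between the two flanking blocks
            diff = (fa != fb)
            for b1, b2 in zip(blocks, blocks[1:]):
                if b1.chromosome != b2.chromosome:
                    continue
                left = [k for k in range(b1.first_index, b1.last_index + 1) if diff[k]]
                right = [k for k in range(b2.first_index, b2.last_index + 1) if diff[k]]
                if left and right:
                    assert paint[left[-1]] != paint[right[0]]


class TestHetStretches:
    def test_homozygous_sample_has_no_stretches(self):
        mm = make_map(10, n_chrom=2)
        stretches, frac = mosaic.detect_het_stretches(
            np.zeros(10, dtype=np.int8), mm
        )
        assert stretches == [] and frac == 0.0

    def test_fully_heterozygous_sample_one_stretch_per_chromosome(self):
        mm = make_map(12, n_chrom=2)
        stretches, frac = mosaic.detect_het_stretches(np.ones(12, dtype=np.int8), mm)
        assert len(stretches) == 2 and frac == 1.0
        assert all(s.n_het == 6 for s in stretches)

    def test_interrupt_budget(self):
        mm = make_map(12, n_chrom=1)
        calls = np.array([1, 1, 0, 1, 1, 0, 0, 1, 1, 1, 0, 0], dtype=np.int8)
        stretches, _ = mosaic.detect_het_stretches(calls, mm, min_run=3, max_interrupt=1)
        # one homozygous interrupt allowed: [0..4] qualifies; the two
        # interrupts before index 7 break the run; [7..9] qualifies
        assert [(s.first_index, s.last_index) for s in stretches] == [(0, 4), (7, 9)]

    def test_missing_calls_are_neutral(self):
        mm = make_map(8, n_chrom=1)
        calls = np.array([1, MISSING, 1, MISSING, 1, 0, 0, 0], dtype=np.int8)
        stretches, _ = mosaic.detect_het_stretches(calls, mm, min_run=3, max_interrupt=0)
        assert [(s.first_index, s.last_index) for s in stretches] == [(0, 4)]


class TestF1Assignment:
    def test_perfect_f1_called_with_correct_pair(self):
        a = np.array([0, 0, 2, 2, 0, 0], dtype=np.int8)
        b = np.array([0, 2, 0, 2, 2, 0], dtype=np.int8)
        child = np.where(a == b, a, 1).astype(np.int8)
        call = mosaic.assign_f1_parents(child, {"A": a, "B": b, "C": a.copy()})
        assert call.verdict == "first_generation"
        assert {call.parent_a, call.parent_b} == {"A", "B"}
        assert call.fraction_heterozygous == 1.0

    def test_child_identical_to_candidate_is_none(self):
        a = np.array([0, 0, 2, 2], dtype=np.int8)
        b = np.array([2, 2, 0, 0], dtype=np.int8)
        call = mosaic.assign_f1_parents(a.copy(), {"A": a, "B": b})
        assert call.verdict == "none"

    def test_partial_heterozygosity_is_later_generation(self):
        a = np.array([0, 0, 0, 0], dtype=np.int8)
        b = np.array([2, 2, 2, 2], dtype=np.int8)
        f2 = np.array([1, 0, 2, 1], dtype=np.int8)  # selfed progeny of an F1
        call = mosaic.assign_f1_parents(f2, {"A": a, "B": b})
        assert call.verdict == "later_generation_or_recombinant"
        assert call.fraction_heterozygous == pytest.approx(0.5)

    def test_four_marker_outcross_detected(self):
        # two nearly identical genotypes differing at only four markers:
        # the outcross is heterozygous at exactly those four
        L = 40
        a = np.zeros(L, dtype=np.int8)
        b = a.copy()
        b[[5, 15, 25, 35]] = 2
        child = a.copy()
        child[[5, 15, 25, 35]] = 1
        call = mosaic.assign_f1_parents(child, {"A": a, "B": b})
        assert call.verdict == "first_generation"
        assert call.n_differentiating == 4


class TestRILReconstruction:
    def test_constructed_single_breakpoint(self):
        mm = make_map(6, n_chrom=1)
        a = np.array([0, 0, 0, 0, 0, 0], dtype=np.int8)
        b = np.array([2, 2, 2, 2, 2, 2], dtype=np.int8)
        rec = np.array([0, 0, 0, 2, 2, 2], dtype=np.int8)
        res = mosaic.reconstruct_ril({"A": a, "B": b, "R": rec}, mm)
        assert res.unexplained["R"] == 0
        assert res.breakpoints["R"] == 1
        np.testing.assert_array_equal(res.paintings["R"], [0, 0, 0, 1, 1, 1])

    def test_unrelated_genotype_counts_unexplained(self):
        mm = make_map(25, n_chrom=1)
        rng = np.random.default_rng(2)
        a = np.zeros(25, dtype=np.int8)
        b = np.full(25, 2, dtype=np.int8)
        rec = np.array([0] * 12 + [2] * 13, dtype=np.int8)
        alien = a.copy()
        # a third pattern: heterozygous calls match neither founder
        alien[:20] = 1
        res = mosaic.reconstruct_ril({"A": a, "B": b, "R": rec, "X": alien}, mm)
        assert res.unexplained["X"] == 20

    def test_simulated_ril_stand_fully_explained(self):
        table, truth = make_ril_stand(n_lines=6, n_markers=60, n_meioses=3, seed=9)
        mm = truth["marker_map"]
        mlgs = {sid: table.calls[i] for i, sid in enumerate(table.sample_ids)}
        res = mosaic.reconstruct_ril(mlgs, mm)
        assert res.total_unexplained == 0
        assert {res.founder_a, res.founder_b} == {"founderA", "founderB"}

    def test_breakpoints_match_exhaustive_minimum(self):
        table, truth = make_ril_stand(
            n_lines=5, n_markers=30, n_differentiating=12, n_meioses=2, seed=11
        )
        mm = truth["marker_map"]
        fa = truth["founders"]["founderA"]
        fb = truth["founders"]["founderB"]
        mlgs = {sid: table.calls[i] for i, sid in enumerate(table.sample_ids)}
        res = mosaic.reconstruct_ril(mlgs, mm)
        for sid in mlgs:
            want = min_breakpoints_exhaustive(
                mlgs[sid], fa, fb, mm.chromosomes
            )
            assert res.breakpoints[sid] == want

    def test_identical_mlgs_rejected(self):
        mm = make_map(4, n_chrom=1)
        g = np.zeros(4, dtype=np.int8)
        with pytest.raises(ValueError):
            mosaic.reconstruct_ril({"A": g, "B": g.copy()}, mm)
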