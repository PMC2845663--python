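"""Diversity and inbreeding estimators against hand-computed and
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from standscape import popgen
from standscape.core import MISSING

from oracles import wc_anova_fstats


class TestHe:
    def test_monomorphic_stand_has_zero_diversity(self):
        he = popgen.expected_heterozygosity(np.zeros((4, 3), dtype=np.int8))
        np.testing.assert_allclose(he, 0.0)

    def test_two_individuals_dosages_zero_one(self):
        # allele counts 3:1 over 4 alleles -> (4/3)(1 - 9/16 - 1/16) = 0.5
        he = popgen.expected_heterozygosity(np.array([[0], [1]], dtype=np.int8))
        assert he[0] == pytest.approx(0.5)

    def test_large_sample_limit_is_half_at_balanced_frequency(self):
        calls = np.array([[0]] * 500 + [[2]] * 500, dtype=np.int8)
        he = popgen.expected_heterozygosity(calls)
        assert he[0] == pytest.approx(0.5, abs=1e-3)

    def test_single_called_individual_gives_nan(self):
        calls = np.array([[0], [MISSING]], dtype=np.int8)
        assert np.isnan(popgen.expected_heterozygosity(calls)[0])


class TestOneMinusQ:
    def test_monotypic_homozygous_stand(self):
        assert popgen.one_minus_q(np.zeros((5, 2), dtype=np.int8))[0] == 0.0

    def test_opposite_homozygotes_share_no_alleles(self):
        omq = popgen.one_minus_q(np.array([[0], [2]], dtype=np.int8))
        assert omq[0] == pytest.approx(1.0)

    def test_dosages_zero_one_enumeration(self):
        # four ordered allele draws: identity probability 1/2
        omq = popgen.one_minus_q(np.array([[0], [1]], dtype=np.int8))
        assert omq[0] == pytest.approx(0.5)


class TestWCFStatistics:
    def test_fully_homozygous_polymorphic_stand_gives_fis_one(self):
        calls = np.array([[0, 2], [2, 0], [0, 0]], dtype=np.int8)
        assert popgen.wc_f_statistics(calls).f_is == pytest.approx(1.0)

    def test_all_heterozygotes_give_negative_fis(self):
        calls = np.ones((6, 1), dtype=np.int8)
        fs = popgen.wc_f_statistics(calls)
        assert fs.f_is == pytest.approx(-1.0)

    def test_opposite_fixation_gives_theta_one(self):
        calls = np.array([[0, 0]] * 5 + [[2, 2]] * 5, dtype=np.int8)
        codes = np.repeat([0, 1], 5)
        assert popgen.wc_f_statistics(calls, codes).f_st == pytest.approx(1.0)

    def test_monomorphic_panel_flagged_undefined(self):
        fs = popgen.wc_f_statistics(np.zeros((4, 3), dtype=np.int8))
        assert fs.n_loci == 0 and np.isnan(fs.f_is)

    def test_matches_anova_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            r = int(rng.integers(1, 5))
            ns = rng.integers(3, 13, size=r)
            L = int(rng.integers(1, 7))
            calls = rng.integers(0, 3, size=(int(ns.sum()), L)).astype(np.int8)
            calls[rng.random(calls.shape) < 0.05] = MISSING
            codes = np.repeat(np.arange(r), ns)
            fs = popgen.wc_f_statistics(calls, codes)
            o_is, o_st, o_it = wc_anova_fstats(calls, codes)
            for got, want in ((fs.f_is, o_is), (fs.f_st, o_st), (fs.f_it, o_it)):
                assert (got != got) == (want != want)
                if got == got:
                    assert got == pytest.approx(want, abs=1e-12)


class TestEffectiveOutcrossing:
    def test_study_headline_values(self):
        assert popgen.outcrossing_percent(0.969) == 1.6
        assert popgen.outcrossing_percent(1.0) == 0.0

    def test_bounds_and_monotonicity(self):
        assert popgen.effective_outcrossing(0.0) == 1.0
        grid = np.linspace(0, 1, 11)
        ocs = [popgen.effective_outcrossing(f) for f in grid]
        assert all(a > b for a, b in zip(ocs, ocs[1:]))

    def test_undefined_at_minus_one(self):
        with pytest.raises(ValueError):
            popgen.effective_outcrossing(-1.0)


class TestAlleleRelabeling:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_he_and_q_invariant_under_allele_swap(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(8, 5)).astype(np.int8)
        swapped = (2 - calls).astype(np.int8)
        np.testing.assert_allclose(
            popgen.expected_heterozygosity(calls),
            popgen.expected_heterozygosity(swapped),
        )
        np.testing.assert_allclose(
            popgen.one_minus_q(calls), popgen.one_minus_q(swapped)
        )
        np.testing.assert_allclose(
            popgen.observed_heterozygosity(calls),
            popgen.observed_heterozygosity(swapped),
        )


class TestSubsampling:
    def test_stand_of_exactly_subsample_size_equals_direct_estimate(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(10, 20)).astype(np.int8)
        res = popgen.subsampled_stand_stats(
            calls, config=popgen.SubsampleConfig(10, 100, 50, seed=0)
        )
        direct_he = popgen.expected_heterozygosity(calls)
        assert res.he == pytest.approx(float(np.nan_to_num(direct_he).mean()))
        direct_fis = popgen.wc_f_statistics(calls).f_is
        assert res.f_is == pytest.approx(direct_fis)

    def test_monotypic_homozygous_stand_flagged(self):
        res = popgen.subsampled_stand_stats(
            np.zeros((15, 8), dtype=np.int8),
            config=popgen.SubsampleConfig(10, 20, 20, seed=0),
        )
        assert res.he == 0.0
        assert np.isnan(res.f_is)

    def test_undersized_stand_rejected(self):
        with pytest.raises(ValueError, match="subsample_size"):
            popgen.subsampled_stand_stats(np.zeros((5, 3), dtype=np.int8))

    def test_subsampled_he_tracks_full_sample_estimate(self):
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(40):
            p = rng.uniform(0.2, 0.5, size=15)
            hap = (rng.random((30, 15)) < p).astype(np.int8)
            calls = (hap * 2).astype(np.int8)  # selfing-like: homozygous
            res = popgen.subsampled_stand_stats(
                calls, config=popgen.SubsampleConfig(10, 50, 10, seed=int(rng.integers(2**31)))
            )
            full = float(np.nan_to_num(popgen.expected_heterozygosity(calls)).mean())
            diffs.append(res.he - full)
        assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 1e-3


class TestYearPairFst:
    def test_identical_year_samples_give_near_zero_theta(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        res = popgen.year_pair_fst(calls, calls.copy(), seed=0, bootstrap_reps=50)
        assert res.theta <= 0.01

    def test_disjoint_fixed_genotypes_give_theta_near_one(self):
        g1 = np.zeros((8, 20), dtype=np.int8)
        g2 = np.full((8, 20), 2, dtype=np.int8)
        res = popgen.year_pair_fst(g1, g2, seed=0, bootstrap_reps=50)
        assert res.theta > 0.95

    def test_resampled_same_population_within_permutation_null(self):
        rng = np.random.default_rng(3)
        pool = rng.integers(0, 3, size=(60, 25)).astype(np.int8)
        y1 = pool[rng.choice(60, 15, replace=False)]
        y2 = pool[rng.choice(60, 25, replace=False)]
        res = popgen.year_pair_fst(y1, y2, n_reps=30, bootstrap_reps=50, seed=0)
        # permutation null: shuffle year labels of the pooled sample
        pooled = np.vstack([y1, y2])
        null = []
        for k in range(100):
            perm = rng.permutation(40)
            a, b = pooled[perm[:15]], pooled[perm[15:]]
            null.append(popgen.year_pair_fst(a, b, n_reps=5, bootstrap_reps=1,
                                             seed=k).theta)
        assert res.theta <= np.quantile(null, 0.975)
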