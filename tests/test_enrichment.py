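"""Positional residue enrichment and hypergeometric subset tests."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from psadpr import (
    build_spec, background_spec, generate_windows, hypergeom_enrichment,
    kinase_subfamily_enrichment, positional_enrichment,
)


class TestPositionalEnrichment:
    def test_identical_sets_yield_nothing(self):
        wins = generate_windows(200, background_spec(), "UM", seed=1)
        result = positional_enrichment(wins, wins)
        assert not result.table.significant.any()

    def test_planted_arginine_recovered(self):
        fg_spec = build_spec(enrich={(-2, "R"): 0.55})
        fg = generate_windows(1000, fg_spec, "pSADPr", seed=2)
        bg = generate_windows(1000, background_spec(), "UM", seed=3)
        sig = positional_enrichment(fg, bg).significant_cells()
        assert sig.get((-2, "R")) == 1

    def test_null_foreground_stays_silent(self):
        # a foreground drawn from the background distribution must not
        # produce Bonferroni-significant cells
        fg = generate_windows(100, background_spec(), "pSADPr", seed=4)
        bg = generate_windows(500, background_spec(), "UM", seed=5)
        result = positional_enrichment(fg, bg)
        assert not result.table.significant.any()

    def test_order_invariance(self):
        fg = generate_windows(300, build_spec(enrich={(3, "K"): 0.4}), "pSADPr",
                              seed=6)
        bg = generate_windows(300, background_spec(), "UM", seed=7)
        rng = np.random.default_rng(0)
        sig1 = positional_enrichment(fg, bg).significant_cells()
        fg2 = [fg[i] for i in rng.permutation(len(fg))]
        bg2 = [bg[i] for i in rng.permutation(len(bg))]
        sig2 = positional_enrichment(fg2, bg2).significant_cells()
        assert sig1 == sig2

    def test_center_position_excluded(self):
        fg = generate_windows(50, background_spec(), "pSADPr", seed=8)
        bg = generate_windows(50, background_spec(), "UM", seed=9)
        table = positional_enrichment(fg, bg).table
        assert 0 not in set(table.position)
        assert len(table) == 800

    def test_padded_positions_excluded_from_frequencies(self):
        # all-padded left flank: frequencies at negative positions undefined
        fg = ["_" * 20 + "S" + "A" * 20] * 30
        bg = ["_" * 20 + "S" + "C" * 20] * 30
        table = positional_enrichment(fg, bg).table
        left = table[table.position < 0]
        assert left.fg_freq.isna().all()
        right = table[(table.position > 0) & (table.residue == "A")]
        assert (right.fg_freq == 1.0).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            positional_enrichment([], ["A" * 20 + "S" + "A" * 20])


class TestHypergeom:
    def test_exact_single_term(self):
        e = hypergeom_enrichment(10, 5, 4, 4)
        assert e.p_enriched == pytest.approx(5 / 210, rel=1e-12)

    def test_expected_value_is_central(self):
        e = hypergeom_enrichment(100, 50, 10, 5)  # k = n*K/N exactly
        assert e.p_enriched >= 0.5

    def test_zero_k_upper_tail_is_one(self):
        assert hypergeom_enrichment(20, 8, 6, 0).p_enriched == 1.0

    def test_tail_identity(self):
        for N, K, n, k in [(30, 11, 9, 4), (50, 25, 12, 6), (15, 3, 7, 1)]:
            e = hypergeom_enrichment(N, K, n, k)
            pmf_k = hypergeom.pmf(k, N, K, n)
            assert e.p_enriched + e.p_depleted - pmf_k == pytest.approx(1.0,
                                                                        abs=1e-9)

    def test_matches_enumeration_oracle_small_grid(self):
        from math import comb

        for N in range(1, 26):
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(0, N + 1, max(1, N // 4)):
                    lo, hi = max(0, n - (N - K)), min(K, n)
                    for k in range(lo, hi + 1):
                        expected = sum(
                            comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1)
                        ) / comb(N, n)
                        got = hypergeom_enrichment(N, K, n, k).p_enriched
                        assert got == pytest.approx(expected, rel=1e-9), (N, K, n, k)

    def test_matches_scipy_on_random_large_cases(self, rng):
        for _ in range(200):
            N = int(rng.integers(2, 50)) + 1
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n - (N - K)), min(K, n)
            k = int(rng.integers(lo, hi + 1))
            got = hypergeom_enrichment(N, K, n, k)
            assert got.p_enriched == pytest.approx(hypergeom.sf(k - 1, N, K, n),
                                                   rel=1e-9, abs=1e-300)
            assert got.p_depleted == pytest.approx(hypergeom.cdf(k, N, K, n),
                                                   rel=1e-9, abs=1e-300)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 12, 4, 2)


class TestKinaseEnrichment:
    def test_planted_agc_like_enrichment(self, rng):
        # subset covered at 68% vs background 44% at realistic sizes
        N, n = 27_728, 2_378
        col = np.zeros(N, dtype=int)
        mask = np.zeros(N, dtype=bool)
        mask[:n] = True
        col[:int(0.68 * n)] = 1  # subset carriers
        rest = rng.permutation(N - n)[:int(0.44 * N) - int(0.68 * n)]
        col[n + rest] = 1
        table = kinase_subfamily_enrichment(col[:, None], mask, ["AGC"])
        assert table.p_enriched[0] < 1e-20
        assert table.subset_fraction[0] == pytest.approx(0.68, abs=0.01)

    def test_all_ones_column_uninformative(self):
        M = np.ones((50, 1), dtype=int)
        mask = np.zeros(50, dtype=bool)
        mask[:10] = True
        table = kinase_subfamily_enrichment(M, mask, ["X"])
        assert table.p_enriched[0] == pytest.approx(1.0)

    def test_uniform_subset_is_null(self, rng):
        # repeated random subsets: Bonferroni-corrected significance is rare
        N, n, n_sub = 500, 100, 6
        M = (rng.random((N, n_sub)) < 0.3).astype(int)
        hits = 0
        reps = 100
        for _ in range(reps):
            mask = np.zeros(N, dtype=bool)
            mask[rng.choice(N, n, replace=False)] = True
            table = kinase_subfamily_enrichment(M, mask)
            hits += int((table.p_enriched < 0.05 / n_sub).any())
        # per-run false-alarm rate is at most ~alpha = 0.05; allow 3 sigma
        assert hits <= reps * 0.05 + 3 * np.sqrt(reps * 0.05 * 0.95)

    def test_mask_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mask"):
            kinase_subfamily_enrichment(np.zeros((10, 2), dtype=int),
                                        np.zeros(9, dtype=bool))

    def test_nonbinary_matrix_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            kinase_subfamily_enrichment(np.full((5, 1), 2), np.zeros(5, bool))
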