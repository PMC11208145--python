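"""HLA shift tests, BH correction and the non-overlap permutation score."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from adnakit.errors import DegenerateTableError, InvalidParameterError
from adnakit.hla import (
    HLAShiftTest,
    NonOverlapTest,
    allele_frequencies,
    bh_adjust,
    compare_cohorts,
    f_adj_star,
    fisher_exact_2x2,
    haplotype_pair_table,
    permutation_null,
)
from adnakit.simulate import simulate_hla_cohorts


def _geno(rows):
    return pd.DataFrame(rows, columns=["sample", "locus", "allele1", "allele2"])


class TestAlleleFrequencies:
    def test_fixed_cohort_frequency_one(self):
        g = _geno([("s1", "DRB1", "DRB1*04:07", "DRB1*04:07"),
                   ("s2", "DRB1", "DRB1*04:07", "DRB1*04:07")])
        t = allele_frequencies(g, "C", "DRB1")
        assert t["freq"].tolist() == [1.0]
        assert t["total"].iloc[0] == 4

    def test_het_plus_distinct_homozygote(self):
        g = _geno([("s1", "A", "A*01:01", "A*02:01"),
                   ("s2", "A", "A*02:01", "A*02:01")])
        t = allele_frequencies(g, "C", "A").set_index("allele")
        assert t.loc["A*01:01", "freq"] == 0.25
        assert t.loc["A*02:01", "freq"] == 0.75

    def test_empty_cohort_gives_empty_table(self):
        t = allele_frequencies(_geno([]), "C", "B")
        assert t.empty

    def test_malformed_allele_name_rejected(self):
        g = _geno([("s1", "A", "A0101", "A*02:01")])
        with pytest.raises(InvalidParameterError):
            allele_frequencies(g, "C", "A")


class TestFisherExact:
    def test_identical_margins_give_p_one(self):
        _, p = fisher_exact_2x2(5, 10, 5, 10)
        assert p == pytest.approx(1.0)

    def test_extreme_table_hand_value(self):
        from math import comb

        _, p = fisher_exact_2x2(10, 10, 0, 10)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_cohort_swap_symmetry(self):
        _, p1 = fisher_exact_2x2(7, 20, 2, 15)
        _, p2 = fisher_exact_2x2(2, 15, 7, 20)
        assert p1 == pytest.approx(p2)

    def test_zero_totals_rejected(self):
        with pytest.raises(InvalidParameterError):
            fisher_exact_2x2(0, 0, 1, 10)

    @staticmethod
    def _enumeration_p(k1, n1, k2, n2):
        # minimum-likelihood two-sided p by full hypergeometric enumeration
        big_n, big_k = n1 + n2, k1 + k2
        lo = max(0, big_k - n2)
        hi = min(big_k, n1)
        xs = np.arange(lo, hi + 1)
        probs = hypergeom.pmf(xs, big_n, big_k, n1)
        p_obs = hypergeom.pmf(k1, big_n, big_k, n1)
        return float(probs[probs <= p_obs * (1 + 1e-9)].sum())

    def test_agrees_with_enumeration_on_all_small_tables(self):
        for n1, n2 in itertools.product(range(1, 9), range(1, 9)):
            for k1 in range(n1 + 1):
                for k2 in range(n2 + 1):
                    _, p = fisher_exact_2x2(k1, n1, k2, n2)
                    assert p == pytest.approx(
                        self._enumeration_p(k1, n1, k2, n2), abs=1e-10
                    ), (k1, n1, k2, n2)

    def test_agrees_with_enumeration_on_random_margins_up_to_30(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n1, n2 = rng.integers(1, 31, size=2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            _, p = fisher_exact_2x2(int(k1), int(n1), int(k2), int(n2))
            assert p == pytest.approx(
                self._enumeration_p(int(k1), int(n1), int(k2), int(n2)), abs=1e-10
            )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_step_up_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @staticmethod
    def _literal_step_up(p):
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.empty(m)
        running = np.inf
        for rank in range(m, 0, -1):
            running = min(running, m * p[order[rank - 1]] / rank)
            q_sorted[rank - 1] = min(running, 1.0)
        q = np.empty(m)
        q[order] = q_sorted
        return q

    @given(st.lists(st.floats(1e-8, 1.0, allow_nan=False), min_size=1, max_size=40))
    def test_matches_literal_step_up(self, p):
        assert np.allclose(bh_adjust(p), self._literal_step_up(p))

    @given(st.lists(st.floats(1e-8, 1.0, allow_nan=False), min_size=2, max_size=40))
    def test_q_monotone_in_sorted_p(self, p):
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(p) - 1e-12).all()


class TestCompareCohorts:
    def test_identical_cohorts_yield_no_significant_shift(self):
        g = _geno(
            [(f"s{i}", "A", "A*01:01", "A*02:01") for i in range(20)]
        )
        out = compare_cohorts(g, g)
        assert not out["significant"].any()
        assert (out["p_raw"] == 1.0).all()

    def test_allele_absent_from_both_not_tested(self):
        g1 = _geno([("s1", "A", "A*01:01", "A*01:01")])
        g2 = _geno([("t1", "A", "A*02:01", "A*02:01")])
        out = compare_cohorts(g1, g2)
        assert set(out["allele"]) == {"A*01:01", "A*02:01"}

    def test_planted_large_shift_detected_with_direction(self):
        pool = pd.DataFrame(
            {
                "A": ["A*01:01", "A*02:01", "A*03:01", "A*24:02"],
                "freq": [0.3, 0.3, 0.2, 0.2],
            }
        )
        out = simulate_hla_cohorts(
            pool, {("A", "A*01:01"): 0.25}, n1=200, n2=200, seed=0
        )
        res = compare_cohorts(out["genotypes1"], out["genotypes2"])
        hit = res[res["allele"] == "A*01:01"].iloc[0]
        assert hit["significant"]
        assert hit["direction"] == "increase"


class TestFAdjStar:
    def test_perfect_non_overlap_is_maximal(self):
        table = np.array([[50, 0], [0, 50]])
        assert f_adj_star(table) == pytest.approx(1.0)

    def test_exact_independence_is_zero(self):
        table = np.array([[25, 25], [25, 25]])
        assert f_adj_star(table) == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_oracle_on_3x3_table(self):
        table = np.array([[30, 5, 0], [2, 20, 8], [0, 3, 12]], dtype=float)

        def oracle(t):
            # literal recomputation: margin-weighted mean min-overlap of
            # conditional rows, then of conditional columns, averaged
            def direction(t):
                p = t / t.sum()
                rows = p.sum(axis=1)
                cond = p / rows[:, None]
                num = den = 0.0
                for i in range(len(rows)):
                    for j in range(i + 1, len(rows)):
                        w = rows[i] * rows[j]
                        num += w * sum(
                            min(cond[i][k], cond[j][k]) for k in range(p.shape[1])
                        )
                        den += w
                return 1 - num / den

            return (direction(t) + direction(t.T)) / 2

        assert f_adj_star(table) == pytest.approx(oracle(table), abs=1e-12)

    def test_invariant_to_allele_relabelling(self):
        rng = np.random.default_rng(4)
        table = rng.integers(0, 20, size=(4, 5)).astype(float)
        table[0, 0] += 5  # ensure non-degenerate
        base = f_adj_star(table)
        perm = table[rng.permutation(4)][:, rng.permutation(5)]
        assert f_adj_star(perm) == pytest.approx(base)

    def test_orientation_symmetric(self):
        rng = np.random.default_rng(5)
        table = rng.integers(1, 20, size=(3, 6)).astype(float)
        assert f_adj_star(table) == pytest.approx(f_adj_star(table.T))

    def test_single_allele_locus_is_undefined(self):
        with pytest.raises(DegenerateTableError):
            f_adj_star(np.array([[10, 20]]))


class TestPermutationNull:
    def test_margins_preserved_in_every_permutation(self):
        table = np.array([[12, 3], [4, 9]])
        row_m = table.sum(axis=1)
        col_m = table.sum(axis=0)
        seen = []

        def spy(t):
            seen.append(np.asarray(t))
            return f_adj_star(t)

        permutation_null(table, n_perm=50, seed=0, statistic=spy)
        for t in seen:
            assert np.array_equal(t.sum(axis=1), row_m)
            assert np.array_equal(t.sum(axis=0), col_m)

    def test_fixed_seed_reproducible(self):
        table = np.array([[12, 3], [4, 9]])
        a = permutation_null(table, n_perm=200, seed=3)
        b = permutation_null(table, n_perm=200, seed=3)
        assert a.sd_units == b.sd_units

    def test_non_overlapping_table_scores_above_null(self):
        table = np.array([[50, 0], [0, 50]])
        score = permutation_null(table, n_perm=200, seed=1)
        assert score.sd_units > 0

    def test_null_calibration_under_independence(self):
        """Tables drawn under independence stay within |sd_units| < 3 in
        >= 99% of seeds."""
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            a = rng.integers(0, 4, size=200)
            b = rng.integers(0, 4, size=200)
            table = np.zeros((4, 4))
            np.add.at(table, (a, b), 1)
            score = permutation_null(table, n_perm=200, seed=seed)
            if abs(score.sd_units) < 3:
                ok += 1
        assert ok >= 0.99 * n_seeds


class TestEndToEnd:
    def test_planted_drb1_like_shift_flagged_in_most_seeds(self):
        """A 0.23 -> 0.46 allele-frequency increase at realistic cohort
        sizes (47 vs 67 individuals) is flagged significant in >= 80% of
        seeds."""
        pool = pd.DataFrame(
            {
                "DRB1": ["DRB1*04:07", "DRB1*08:02", "DRB1*14:02", "DRB1*04:11"],
                "DQB1": ["DQB1*03:02", "DQB1*04:02", "DQB1*03:01", "DQB1*03:02"],
                "freq": [0.23, 0.33, 0.24, 0.20],
            }
        )
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            out = simulate_hla_cohorts(
                pool, {("DRB1", "DRB1*04:07"): 0.23}, n1=47, n2=67, seed=seed
            )
            res = compare_cohorts(out["genotypes1"], out["genotypes2"])
            row = res[res["allele"] == "DRB1*04:07"]
            if len(row) and row.iloc[0]["significant"] and (
                row.iloc[0]["direction"] == "increase"
            ):
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_locus_pair_scan_reports_all_pairs(self):
        hap_rows = []
        rng = np.random.default_rng(6)
        for s in range(30):
            for h in (1, 2):
                hap_rows.append((f"s{s}", h, "A", f"A*{rng.integers(1, 4):02d}:01"))
                hap_rows.append((f"s{s}", h, "B", f"B*{rng.integers(1, 4):02d}:01"))
                hap_rows.append((f"s{s}", h, "C", "C*01:02"))  # degenerate locus
        haps = pd.DataFrame(
            hap_rows, columns=["sample", "haplotype_index", "locus", "allele"]
        )
        table = NonOverlapTest(haps, n_perm=100, seed=0).fit()
        assert len(table) == 3  # AB, AC, BC
        ab = table[(table["locus_1"] == "A") & (table["locus_2"] == "B")].iloc[0]
        assert np.isfinite(ab["sd_units"])
        ac = table[(table["locus_1"] == "A") & (table["locus_2"] == "C")].iloc[0]
        assert np.isnan(ac["f_adj_star"])  # single-allele locus undefined

    def test_haplotype_pair_table_counts(self):
        haps = pd.DataFrame(
            [
                ("s1", 1, "A", "A*01:01"), ("s1", 1, "B", "B*07:02"),
                ("s1", 2, "A", "A*02:01"), ("s1", 2, "B", "B*08:01"),
                ("s2", 1, "A", "A*01:01"), ("s2", 1, "B", "B*07:02"),
                ("s2", 2, "A", "A*01:01"), ("s2", 2, "B", "B*08:01"),
            ],
            columns=["sample", "haplotype_index", "locus", "allele"],
        )
        t = haplotype_pair_table(haps, "A", "B")
        assert t.loc["A*01:01", "B*07:02"] == 2
        assert t.loc["A*01:01", "B*08:01"] == 1
        assert t.loc["A*02:01", "B*08:01"] == 1
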