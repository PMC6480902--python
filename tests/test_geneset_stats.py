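"""Match-table construction, permutation test, sign tests, top-decile."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import make_summary_from_ratios
from ovage import geneset_stats as gs
from ovage import synthetic_data as sd
from ovage.io_formats import GeneSet, ValidationError


def _summary(expr: pd.Series, ratios_a=None, ratios_b=None):
    idx = expr.index
    zeros = pd.Series(0.0, index=idx)
    return make_summary_from_ratios(
        {"A": zeros if ratios_a is None else ratios_a,
         "B": zeros if ratios_b is None else ratios_b},
        expr,
    )


class TestMatchTable:
    def test_median_ranked_gene_matches_adjacent_ranks(self):
        # 1,001 genes with strictly decreasing expression; focal at the median
        idx = pd.Index([f"g{i:04d}" for i in range(1001)])
        expr = pd.Series(np.linspace(1000, 1, 1001), index=idx)
        focal = GeneSet("f", (idx[500],))
        table = gs.build_match_table(_summary(expr), focal)
        expected = [f"g{i:04d}" for i in range(490, 500)] + [
            f"g{i:04d}" for i in range(501, 511)
        ]
        assert list(table.matches[idx[500]]) == expected

    def test_top_ranked_focal_gene_takes_all_matches_from_below(self):
        idx = pd.Index([f"g{i:03d}" for i in range(100)])
        expr = pd.Series(np.linspace(100, 1, 100), index=idx)
        table = gs.build_match_table(_summary(expr), GeneSet("f", (idx[0],)))
        assert list(table.matches[idx[0]]) == [f"g{i:03d}" for i in range(1, 21)]

    def test_focal_members_never_used_as_matches(self):
        rng = np.random.default_rng(0)
        idx = pd.Index([f"g{i:03d}" for i in range(120)])
        expr = pd.Series(rng.gamma(2, 10, 120), index=idx)
        focal = GeneSet("f", tuple(rng.choice(idx, 15, replace=False)))
        table = gs.build_match_table(_summary(expr), focal)
        members = set(focal.members)
        for m in table.matches.values():
            assert len(m) == 20
            assert not members & set(m)

    def test_matches_equal_brute_force_sort_and_scan(self):
        rng = np.random.default_rng(1)
        idx = pd.Index([f"g{i:03d}" for i in range(200)])
        expr = pd.Series(rng.gamma(2, 10, 200), index=idx)
        focal = GeneSet("f", tuple(rng.choice(idx, 12, replace=False)))
        table = gs.build_match_table(_summary(expr), focal, k_up=4, k_down=4)
        # oracle: sort all genes by (-expr, id); scan outward from the focal
        order = sorted(idx, key=lambda g: (-expr[g], g))
        members = set(focal.members)
        for gene in focal.members:
            pos = order.index(gene)
            above = [g for g in order[:pos] if g not in members]
            below = [g for g in order[pos + 1:] if g not in members]
            take_up = above[-4:]
            take_down = below[: 8 - len(take_up)]
            if len(take_down) < 8 - len(take_up):  # deficit below: backfill above
                need = 8 - len(take_down)
                take_up = above[-need:]
            expected = set(take_up) | set(take_down)
            assert set(table.matches[gene]) == expected


class TestPermutationTest:
    def test_identical_ratios_everywhere_give_p_one(self):
        idx = pd.Index([f"g{i}" for i in range(50)])
        expr = pd.Series(np.linspace(50, 1, 50), index=idx)
        ratios = pd.Series(0.7, index=idx)
        summary = _summary(expr, ratios, ratios)
        focal = GeneSet("f", tuple(idx[:5]))
        table = gs.build_match_table(summary, focal, k_up=3, k_down=3)
        out = gs.matched_permutation_test(summary, table, focal, n_perm=500, seed=1)
        assert out.p == 1.0
        assert out.exceedances == 500

    def test_seed_reproduces_exceedance_counts_exactly(self, small_summary, small_sim):
        focal = next(s for s in small_sim.gene_sets if s.name == "pirna")
        table = gs.build_match_table(small_summary, focal)
        a = gs.matched_permutation_test(small_summary, table, focal, n_perm=1000, seed=5)
        b = gs.matched_permutation_test(small_summary, table, focal, n_perm=1000, seed=5)
        assert a.exceedances == b.exceedances
        assert a.p == b.p

    def test_add_one_estimator_never_zero(self, small_summary, small_sim):
        focal = next(s for s in small_sim.gene_sets if s.name == "pirna")
        table = gs.build_match_table(small_summary, focal)
        out = gs.matched_permutation_test(small_summary, table, focal, n_perm=500, seed=2)
        assert out.p > 0.0

    @pytest.mark.parametrize("combine", ["mean", "all_strains"])
    def test_monte_carlo_matches_exhaustive_enumeration(self, combine):
        """3 focal genes x 2 matches: exact p over all 8 assignments, for
        both exceedance rules."""
        rng = np.random.default_rng(3)
        focal_ids = ["f1", "f2", "f3"]
        match_ids = [f"m{i}" for i in range(6)]
        idx = pd.Index(focal_ids + match_ids)
        ra = pd.Series(rng.normal(0, 0.5, len(idx)), index=idx)
        rb = pd.Series(rng.normal(0, 0.5, len(idx)), index=idx)
        expr = pd.Series(np.linspace(9, 1, len(idx)), index=idx)
        summary = _summary(expr, ra, rb)
        table = gs.MatchTable(
            {"f1": ("m0", "m1"), "f2": ("m2", "m3"), "f3": ("m4", "m5")}, 2, 0
        )
        focal = GeneSet("f", tuple(focal_ids))
        obs_a, obs_b = ra[focal_ids].mean(), rb[focal_ids].mean()
        hits = total = 0
        for combo in itertools.product(range(2), repeat=3):
            chosen = [table.matches[f][j] for f, j in zip(focal_ids, combo)]
            total += 1
            na, nb = ra[chosen].mean(), rb[chosen].mean()
            if combine == "mean":
                hits += (na + nb) / 2 >= (obs_a + obs_b) / 2
            else:
                hits += na >= obs_a and nb >= obs_b
        exact = hits / total
        out = gs.matched_permutation_test(
            summary, table, focal, n_perm=10_000, seed=4, combine=combine
        )
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(out.p_raw - exact) <= 3 * se + 1e-12

    def test_empty_focal_set_rejected(self, small_summary):
        with pytest.raises(ValidationError):
            gs.matched_permutation_test(
                small_summary, gs.MatchTable({}, 1, 0), GeneSet("f", ()), seed=1
            )

    def test_seed_required(self, small_summary, small_sim):
        focal = next(s for s in small_sim.gene_sets if s.name == "pirna")
        table = gs.build_match_table(small_summary, focal)
        with pytest.raises(ValidationError, match="seed"):
            gs.matched_permutation_test(small_summary, table, focal, n_perm=100)


class TestDirectionCount:
    def test_hand_pooled_counts(self):
        idx = pd.Index(["a", "b", "c"])
        ratios = pd.Series([1.0, 1.0, -1.0], index=idx)
        summary = _summary(pd.Series([3.0, 2.0, 1.0], index=idx), ratios, ratios)
        out = gs.direction_count(summary, GeneSet("s", ("a", "b", "c")))
        assert tuple(out.loc["pooled"]) == (2, 1, 0)

    def test_all_zero_ratios_are_flat(self):
        idx = pd.Index(["a", "b", "c"])
        summary = _summary(pd.Series([3.0, 2.0, 1.0], index=idx))
        out = gs.direction_count(summary, GeneSet("s", ("a", "b", "c")))
        assert tuple(out.loc["pooled"]) == (0, 0, 3)

    def test_against_sign_loop_oracle(self):
        rng = np.random.default_rng(5)
        idx = pd.Index([f"g{i}" for i in range(40)])
        ra = pd.Series(rng.normal(size=40), index=idx)
        rb = pd.Series(rng.normal(size=40), index=idx)
        summary = _summary(pd.Series(rng.gamma(2, 5, 40), index=idx), ra, rb)
        members = tuple(rng.choice(idx, 15, replace=False))
        out = gs.direction_count(summary, GeneSet("s", members))
        n_up = sum(1 for g in members if ra[g] > 0)
        n_down = sum(1 for g in members if ra[g] < 0)
        assert tuple(out.loc["A"]) == (n_up, n_down, 15 - n_up - n_down)


class TestSignTest:
    def test_severe_imbalance_below_printed_bound(self):
        assert gs.sign_test(47, 49) < 1e-10

    def test_balanced_capped_at_one(self):
        assert gs.sign_test(2, 4) == 1.0

    def test_hand_doubled_tail(self):
        # 4 of 5 down: 2 * (C(5,0) + C(5,1)) / 2^5 = 0.375
        assert gs.sign_test(4, 5) == pytest.approx(0.375)

    def test_matches_exact_binomial_oracle_all_n_up_to_60(self):
        for n in range(1, 61):
            for k in range(0, n + 1):
                tail = min(k, n - k)
                exact = min(2.0 * sum(scipy.stats.binom.pmf(i, n, 0.5) for i in range(tail + 1)), 1.0)
                assert gs.sign_test(k, n) == pytest.approx(exact, rel=1e-9), (k, n)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            gs.sign_test(3, 0)
        with pytest.raises(ValidationError):
            gs.sign_test(5, 4)


class TestTopKEnrichment:
    def test_fraction_one_rejected(self, small_sim, small_de):
        focal = next(s for s in small_sim.gene_sets if s.name == "pirna")
        with pytest.raises(ValidationError):
            gs.topk_enrichment(small_de, focal, top_fraction=1.0)

    def test_set_concentrated_in_top_decile_is_significant(self, small_de):
        de = small_de
        ranked = de.table.sort_values(["padj_age", "p_age"]).index
        planted = GeneSet("top", tuple(ranked[:25]))
        _, chi2, p = gs.topk_enrichment(de, planted)
        assert p < 1e-6

    def test_independent_set_not_enriched(self, small_de):
        de = small_de
        rng = np.random.default_rng(6)
        tested = de.table[de.table["p_age"].notna()].index
        random_set = GeneSet("r", tuple(rng.choice(tested, 30, replace=False)))
        ct, chi2, p = gs.topk_enrichment(de, random_set)
        assert ct.a + ct.c == 30
        assert chi2 < 15  # no systematic enrichment signal
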