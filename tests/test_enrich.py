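"""The five competitive tests, checked against hand values and brute-force
independent oracles (exhaustive enumeration for the hypergeometric test,
a naive two-level permutation scheme for ARTP)."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from pathrank import (
    GeneScores,
    NullDistribution,
    artp_pvalue,
    fisher_pvalue,
    fisher_statistic,
    gsea_es,
    gsea_pvalue,
    hypergeometric_test,
    permutation_pvalue,
    rtp_statistic,
    significant_gene_list,
    tsm_pvalue,
    tsm_statistic,
)
from pathrank.enrich import (
    ArtpNull,
    _es_from_positions,
    hypergeometric_pvalue,
    make_tsm_null,
    results_to_frame,
    sample_rank_rows,
    write_results,
)


class TestPermutationPvalue:
    def test_observed_beats_all_nulls(self):
        nulls = NullDistribution(np.arange(999), scheme="permutation", direction="large")
        assert permutation_pvalue(1e9, nulls) == pytest.approx(1 / 1000)

    def test_observed_at_median(self):
        nulls = NullDistribution(np.arange(999), scheme="permutation", direction="large")
        # ties with the median value count as extreme: (1 + 500) / 1000
        assert permutation_pvalue(499.0, nulls) == pytest.approx(0.501)

    def test_small_direction(self):
        nulls = NullDistribution(np.arange(999), scheme="permutation", direction="small")
        assert permutation_pvalue(-1.0, nulls) == pytest.approx(1 / 1000)

    def test_empty_null_rejected(self):
        nulls = NullDistribution(np.array([]), scheme="permutation")
        with pytest.raises(ValueError, match="empty"):
            permutation_pvalue(0.0, nulls)

    def test_super_uniform_when_exchangeable(self, rng):
        # observed drawn from the same distribution as the nulls
        reps, B = 10_000, 99
        draws = rng.normal(size=(reps, B + 1))
        nulls_sorted = np.sort(draws[:, 1:], axis=1)
        counts = B - np.array(
            [np.searchsorted(nulls_sorted[i], draws[i, 0], side="left")
             for i in range(reps)]
        )
        p = (1.0 + counts) / (B + 1.0)
        for alpha in (0.01, 0.05, 0.1):
            se = math.sqrt(alpha * (1 - alpha) / reps)
            assert (p <= alpha).mean() <= alpha + 3 * se


class TestFisher:
    @pytest.mark.parametrize(
        "u,expected",
        [
            ((1.0, 1.0), 0.0),
            ((0.1, 0.2), 7.8240460),
            ((math.exp(-1),), 2.0),
        ],
    )
    def test_statistic(self, u, expected):
        assert fisher_statistic(u) == pytest.approx(expected, rel=1e-6)

    def test_statistic_rejects_zero(self):
        with pytest.raises(ValueError):
            fisher_statistic([0.0, 0.5])

    def test_asymptotic_pvalue_chi2(self):
        # universe where the pathway has scaled ranks 0.1 and 0.2
        scores = GeneScores.from_pvalues(np.arange(1, 11) / 20.0)
        r = fisher_pvalue(scores, [0, 1], mode="asymptotic")
        assert r.statistic == pytest.approx(7.8240460, rel=1e-6)
        assert r.pvalue == pytest.approx(stats.chi2.sf(7.8240460, 4), rel=1e-6)
        assert r.pvalue == pytest.approx(0.0983, abs=5e-4)

    def test_all_ranks_one_gives_p_one(self):
        scores = GeneScores.from_pvalues(np.array([0.9, 0.1]))
        r = fisher_pvalue(scores, [0], mode="asymptotic")  # gene 0 has rank 1.0
        assert r.statistic == 0.0
        assert r.pvalue == pytest.approx(1.0)

    def test_permutation_needs_enough_replicates(self, uniform_scores):
        with pytest.raises(ValueError, match="B >="):
            fisher_pvalue(uniform_scores, np.arange(5), "permutation", B=50)

    def test_asymptotic_agrees_with_permutation_under_null(self, uniform_scores, rng):
        # the chi-square reference stays accurate despite rank discreteness
        B, L = 500, 15
        diffs = []
        for i in range(60):
            pw = rng.choice(uniform_scores.K, L, replace=False)
            pa = fisher_pvalue(uniform_scores, pw, "asymptotic").pvalue
            pp = fisher_pvalue(uniform_scores, pw, "permutation", B=B, seed=i).pvalue
            se = math.sqrt(max(pa * (1 - pa), 1e-6) / B)
            assert abs(pp - pa) < 4 * se + 2 / (B + 1)
            diffs.append(pp - pa)
        assert abs(np.mean(diffs)) < 0.01


def hypergeom_by_enumeration(K, L, n, k):
    """Exact upper-tail p by enumerating all C(K, n) significant lists."""
    pathway = set(range(L))
    hits = 0
    total = 0
    for lst in itertools.combinations(range(K), n):
        total += 1
        if len(pathway & set(lst)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_hand_example(self):
        assert hypergeometric_test(10, 4, 5, 3) == pytest.approx(66 / 252)

    def test_k_zero_gives_one(self):
        assert hypergeometric_test(100, 10, 20, 0) == pytest.approx(1.0)

    def test_degenerate_universe(self):
        # K == L forces k == n, and the whole support is the single outcome
        assert hypergeometric_test(8, 8, 3, 3) == pytest.approx(1.0)

    @pytest.mark.parametrize("K,L,n", [(8, 3, 4), (10, 4, 5), (12, 5, 3), (9, 2, 6)])
    def test_matches_exhaustive_enumeration(self, K, L, n):
        for k in range(min(L, n) + 1):
            assert hypergeometric_test(K, L, n, k) == pytest.approx(
                hypergeom_by_enumeration(K, L, n, k), abs=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_test(10, 4, 5, 6)
        with pytest.raises(ValueError):
            hypergeometric_test(10, 12, 5, 1)

    def test_significant_gene_list_rules(self, named_scores):
        genes, n = significant_gene_list(named_scores, alpha=0.05)
        assert genes == {"gA"} and n == 1
        genes, n = significant_gene_list(named_scores, top_n=2)
        assert genes == {"gA", "gD"} and n == 2
        with pytest.raises(ValueError):
            significant_gene_list(named_scores, top_n=6)
        with pytest.raises(ValueError):
            significant_gene_list(named_scores)

    def test_top_n_exact_count_with_ties(self, rng):
        scores = GeneScores.from_pvalues(rng.choice([0.1, 0.5], size=20_000))
        _, n = significant_gene_list(scores, top_n=2000)
        assert n == 2000

    def test_pathway_pvalue_top_n(self, uniform_scores):
        r = hypergeometric_pvalue(uniform_scores, np.arange(10), top_n=200)
        k = r.extras["k"]
        assert r.pvalue == pytest.approx(
            hypergeometric_test(uniform_scores.K, 10, 200, k)
        )


class TestTSM:
    def test_expected_order_statistics_give_zero(self):
        L = 7
        u = np.arange(1, L + 1) / (L + 1)
        assert tsm_statistic(u) == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        assert tsm_statistic([0.1, 0.2]) == pytest.approx(0.7)

    def test_limit_all_small(self):
        assert tsm_statistic([1e-15, 1e-15, 1e-15]) == pytest.approx(1.0, abs=1e-9)

    def test_normal_mode_symmetric_null(self):
        # TS = 0 sits at the centre of the N(0, 1/L) reference
        L = 10
        scores = GeneScores.from_pvalues(np.linspace(0.01, 0.99, 110))
        # pathway at sorted positions 10, 20, ..., 100 of the 110-gene
        # universe: sorted ranks are exactly k/(L+1) = 10k/110
        pw = np.arange(9, 100, 10)
        r = tsm_pvalue(scores, pw, mode="normal")
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.pvalue == pytest.approx(0.5)

    def test_empirical_mode_calibrated(self, rng):
        # rejection rate within 3 SE of alpha for uniform inputs
        L, reps, alpha = 12, 2000, 0.05
        null = make_tsm_null(L, R=20_000, seed=1)
        ts = np.array([
            tsm_statistic(np.sort(rng.random(L))) for _ in range(reps)
        ])
        pvals = np.array([permutation_pvalue(t, null) for t in ts])
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs((pvals <= alpha).mean() - alpha) < 3 * se

    def test_small_null_rejected(self, uniform_scores):
        with pytest.raises(ValueError):
            tsm_pvalue(uniform_scores, np.arange(5), mode="empirical", R_or_B=50)


class TestGSEA:
    def test_hand_example(self):
        # gene stats (3,2,1,0.5) ranked; pathway at positions 1 and 3
        scores = GeneScores.from_pvalues(np.exp(-np.array([3.0, 2.0, 1.0, 0.5])))
        es, pos = gsea_es(scores, [0, 2])
        assert list(pos) == [0, 2]
        assert es == pytest.approx(0.75)

    def test_all_top_equal_stats_give_one(self):
        p = np.array([0.01] * 3 + [0.5, 0.6, 0.7])
        scores = GeneScores.from_pvalues(p)
        es, _ = gsea_es(scores, [0, 1, 2])
        assert es == pytest.approx(1.0)

    def test_bottom_pathway_scores_lower(self, rng):
        p = np.sort(rng.random(50))
        scores = GeneScores.from_pvalues(p)
        es_top, _ = gsea_es(scores, np.arange(5))
        es_bot, _ = gsea_es(scores, np.arange(45, 50))
        assert es_bot < es_top
        assert es_bot < 1.0

    def test_degenerate_universe_rejected(self, named_scores):
        with pytest.raises(ValueError):
            gsea_es(named_scores, ["gA", "gB", "gC", "gD", "gE"])

    def test_fast_null_matches_full_running_sum(self, rng):
        """The hits-only ES kernel equals the explicit running-sum ES."""
        K = 300
        scores = GeneScores.from_pvalues(rng.random(K))
        t_desc = -np.log(np.sort(scores.pvalues))
        for L in (1, 5, 40):
            for _ in range(20):
                subset = rng.choice(K, L, replace=False)
                es_full, pos = gsea_es(scores, subset)
                es_fast = _es_from_positions(pos[None, :], t_desc, K)[0]
                # explicit walk as an extra, third route
                walk = np.full(K, -1.0 / (K - L))
                w = t_desc[pos]
                walk[pos] = w / w.sum()
                assert es_full == pytest.approx(np.cumsum(walk).max(), abs=1e-12)
                assert es_fast == pytest.approx(es_full, abs=1e-12)

    def test_pvalue_extreme_observed(self, rng):
        p = np.concatenate([np.full(5, 1e-8), rng.uniform(0.2, 1.0, 995)])
        scores = GeneScores.from_pvalues(p)
        r = gsea_pvalue(scores, np.arange(5), B=999, seed=0)
        assert r.pvalue == pytest.approx(1 / 1000)


class TestRTP:
    def test_direct_products(self):
        assert rtp_statistic([0.1, 0.2], 1) == pytest.approx(0.1)
        assert rtp_statistic([0.1, 0.2], 2) == pytest.approx(0.02)

    def test_full_truncation_equals_fisher(self, rng):
        for _ in range(25):
            u = np.sort(rng.random(8))
            W = rtp_statistic(u, 8)
            assert -2.0 * math.log(W) == pytest.approx(
                fisher_statistic(u), rel=1e-12
            )

    def test_unsorted_and_bad_j_rejected(self):
        with pytest.raises(ValueError):
            rtp_statistic([0.2, 0.1], 1)
        with pytest.raises(ValueError):
            rtp_statistic([0.1, 0.2], 3)


def artp_two_level_oracle(u_obs, K, B_outer, B_inner, rng):
    """Naive nested-permutation ARTP: an independent brute-force oracle.

    The observed min-p statistic and each outer replicate's min-p are all
    estimated with their own fresh inner permutation layer.
    """
    L = u_obs.size

    def min_p(u_sorted, inner_rows):
        w = np.cumsum(np.log(u_sorted))
        w_null = np.cumsum(np.log((inner_rows + 1) / K), axis=1)
        phat = [
            (1 + np.count_nonzero(w_null[:, j] <= w[j])) / (B_inner + 1)
            for j in range(L)
        ]
        return min(phat)

    obs = min_p(u_obs, sample_rank_rows(rng, B_inner, L, K))
    outer = np.empty(B_outer)
    for b in range(B_outer):
        u_b = np.sort((sample_rank_rows(rng, 1, L, K)[0] + 1) / K)
        outer[b] = min_p(u_b, sample_rank_rows(rng, B_inner, L, K))
    return (1 + np.count_nonzero(outer <= obs)) / (B_outer + 1)


class TestARTP:
    def test_single_gene_reduces_to_rank_permutation_test(self, rng):
        scores = GeneScores.from_pvalues(rng.random(200))
        pw = [int(np.argmin(scores.pvalues))]
        r = artp_pvalue(scores, pw, B=500, seed=3)
        # rebuild the same null draws and compare to the plain permutation
        rows = sample_rank_rows(np.random.default_rng(3), 500, 1, 200)
        nulls = NullDistribution(
            (rows[:, 0] + 1) / 200, scheme="permutation", direction="small"
        )
        assert r.pvalue == pytest.approx(
            permutation_pvalue(scores.scaled_ranks[pw[0]], nulls)
        )
        assert r.extras["j_hat"] == 1

    def test_truncation_at_L_reproduces_fisher_permutation(self, uniform_scores, rng):
        for seed in range(5):
            pw = rng.choice(uniform_scores.K, 6, replace=False)
            r_artp = artp_pvalue(
                uniform_scores, pw, B=300, seed=seed, truncation_points=[6]
            )
            r_fm = fisher_pvalue(uniform_scores, pw, "permutation", B=300, seed=seed)
            assert r_artp.pvalue == pytest.approx(r_fm.pvalue, abs=1e-12)

    def test_matches_two_level_oracle(self, rng):
        """Ge's single-level scheme agrees with naive nested permutation."""
        K, L = 60, 3
        scores = GeneScores.from_pvalues(rng.random(K))
        pw = np.argsort(scores.pvalues)[[0, 4, 20]]  # moderately enriched
        p_single = np.mean([
            artp_pvalue(scores, pw, B=200, seed=s).pvalue for s in range(20)
        ])
        p_oracle = artp_two_level_oracle(
            np.sort(scores.scaled_ranks[pw]), K, B_outer=400, B_inner=400, rng=rng
        )
        assert abs(p_single - p_oracle) < 0.02

    def test_empirical_uniform_variant(self, uniform_scores):
        r = artp_pvalue(
            uniform_scores, np.arange(8), B=200, null_source="empirical_uniform",
            seed=0,
        )
        assert r.method == "artp_e"
        assert 1 / 201 <= r.pvalue <= 1.0

    def test_bad_arguments(self, uniform_scores):
        with pytest.raises(ValueError):
            artp_pvalue(uniform_scores, np.arange(5), B=50)
        with pytest.raises(ValueError):
            artp_pvalue(uniform_scores, np.arange(5), B=200, null_source="bootstrap")

    def test_cached_null_close_to_exact(self, uniform_scores, rng):
        null = ArtpNull.from_permutation(uniform_scores.K, 10, B=999, seed=7)
        for _ in range(10):
            pw = rng.choice(uniform_scores.K, 10, replace=False)
            u = np.sort(uniform_scores.scaled_ranks[pw])
            p_fast, _ = null.pvalue(u)
            p_exact = artp_pvalue(uniform_scores, pw, B=999, seed=7).pvalue
            assert abs(p_fast - p_exact) < 0.05


class TestSuperUniformity:
    """Permutation p-values of all tests are super-uniform under the
    competitive null (pathway drawn uniformly at random)."""

    @pytest.mark.parametrize("method", ["fm_perm", "gsea", "artp", "tsm_e"])
    def test_random_pathways(self, method, rng):
        K, L, B, reps = 400, 8, 200, 2000
        scores = GeneScores.from_pvalues(rng.random(K))
        tsm_null = make_tsm_null(L, R=20_000, seed=11)
        artp_null = ArtpNull.from_permutation(K, L, B=999, seed=12)
        pvals = np.empty(reps)
        for i in range(reps):
            pw = rng.choice(K, L, replace=False)
            if method == "fm_perm":
                pvals[i] = fisher_pvalue(scores, pw, "permutation", B, seed=i).pvalue
            elif method == "gsea":
                pvals[i] = gsea_pvalue(scores, pw, B=B, seed=i).pvalue
            elif method == "artp":
                pvals[i] = artp_null.pvalue(scores.scaled_ranks[pw])[0]
            else:
                pvals[i] = tsm_pvalue(
                    scores, pw, "empirical", null=tsm_null
                ).pvalue
        for alpha in (0.01, 0.05, 0.1):
            se = math.sqrt(alpha * (1 - alpha) / reps)
            assert (pvals <= alpha).mean() <= alpha + 3 * se


class TestResultsTable:
    def test_round_trip(self, tmp_path, uniform_scores):
        rs = [
            fisher_pvalue(uniform_scores, np.arange(5), pathway_name="pw1"),
            hypergeometric_pvalue(uniform_scores, np.arange(5), top_n=100,
                                  pathway_name="pw1"),
        ]
        df = results_to_frame(rs)
        assert list(df["method"]) == ["fm_asymptotic", "hypergeometric"]
        out = tmp_path / "results.tsv"
        write_results(rs, out)
        assert out.read_text().startswith("pathway\tmethod\tL\tstatistic\tpvalue")
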