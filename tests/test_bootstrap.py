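"""Weighted bootstrap: weights, draws, statistics, CIs, p-values, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teboot.bootstrap import (
    BootstrapConfig,
    adjust_bh,
    ci_from_bootstrap,
    compute_sampling_weights,
    draw_matched_sets,
    iteration_statistics,
    log2_change_to_percent,
    pvalue_from_bootstrap,
    run_bootstrap,
)
from teboot.intersect import GeneSetPair, GeneTEProfile
from teboot.models import ConfigurationError, ExpressionTable, ValidationError

FOCAL = ("SINE", "ss")


def profile(gid, counts, length_bin=1):
    return GeneTEProfile(gene_id=gid, species="sp", gene_length=1000,
                         length_bin=length_bin, te_counts=counts)


def make_pair(test_strata, ref_strata):
    """Pools from {stratum_counts_dict: n_genes} specs; strata given as
    tuples of (class, age) elements (other than the focal one)."""
    test, ref, i = [], [], 0
    for elements, n in test_strata:
        for _ in range(n):
            counts = {e: 1 for e in elements}
            counts[FOCAL] = 1
            test.append(profile(f"t{i}", counts)); i += 1
    for elements, n in ref_strata:
        for _ in range(n):
            ref.append(profile(f"r{i}", {e: 1 for e in elements})); i += 1
    return GeneSetPair(focal=FOCAL, species="sp", universe="ortholog",
                       test_pool=test, reference_pool=ref)


class TestSamplingWeights:
    def test_frequency_ratio_definition(self):
        # test strata {A: 0.5, B: 0.5}, ref strata {A: 0.25, B: 0.75}
        A, B = (), (("LINE", "ns"),)
        pair = make_pair([(A, 10), (B, 10)], [(A, 5), (B, 15)])
        w, dropped = compute_sampling_weights(pair.test_pool,
                                              pair.reference_pool, FOCAL)
        assert dropped == []
        # per-gene weights proportional to 2 (stratum A) and 2/3 (stratum B)
        assert np.allclose(w[:5] / w[5], 2 / (2 / 3))
        assert np.isclose(w.sum(), 1.0)
        # stratum masses reproduce the test frequencies
        assert np.isclose(w[:5].sum(), 0.5) and np.isclose(w[5:].sum(), 0.5)

    def test_identical_strata_give_uniform_weights(self):
        A, B = (), (("DNA", "ss"),)
        pair = make_pair([(A, 6), (B, 6)], [(A, 8), (B, 8)])
        w, _ = compute_sampling_weights(pair.test_pool, pair.reference_pool,
                                        FOCAL)
        assert np.allclose(w, 1 / 16)

    def test_uncovered_stratum_dropped_and_renormalized(self):
        A, B, C = (), (("DNA", "ss"),), (("LINE", "ss"),)
        pair = make_pair([(A, 5), (C, 5)], [(A, 10), (B, 10)])
        w, dropped = compute_sampling_weights(pair.test_pool,
                                              pair.reference_pool, FOCAL)
        assert len(dropped) == 1 and "LINE" in dropped[0]
        # all mass moves to stratum A; stratum-B ref genes unreachable
        assert np.allclose(w[:10], 0.1) and np.allclose(w[10:], 0.0)

    def test_empty_reference_pool_rejected(self):
        pair = make_pair([((), 5)], [])
        with pytest.raises(ValidationError, match="reference pool"):
            compute_sampling_weights(pair.test_pool, pair.reference_pool, FOCAL)

    def test_focal_element_ignored_when_matching(self):
        # test genes carry focal + LINE:ns; ref genes carry LINE:ns only:
        # after excluding the focal element the strata coincide
        pair = make_pair([((("LINE", "ns"),), 4)], [((("LINE", "ns"),), 4)])
        w, dropped = compute_sampling_weights(pair.test_pool,
                                              pair.reference_pool, FOCAL)
        assert dropped == [] and np.allclose(w, 0.25)


class TestDraws:
    def test_sample_sizes_capped_at_set_size(self):
        pair = make_pair([((), 3000)], [((), 3000)])
        w, _ = compute_sampling_weights(pair.test_pool, pair.reference_pool,
                                        FOCAL)
        cfg = BootstrapConfig(n_iterations=10)
        t, r = draw_matched_sets(pair, w, cfg, np.random.default_rng(0))
        assert len(t) == len(r) == 1000

    def test_small_pool_uses_pool_size(self):
        pair = make_pair([((), 700)], [((), 2000)])
        w, _ = compute_sampling_weights(pair.test_pool, pair.reference_pool,
                                        FOCAL)
        t, r = draw_matched_sets(pair, w, BootstrapConfig(),
                                 np.random.default_rng(0))
        assert len(t) == len(r) == 700

    def test_pool_below_minimum_skips(self):
        pair = make_pair([((), 599)], [((), 2000)])
        w, _ = compute_sampling_weights(pair.test_pool, pair.reference_pool,
                                        FOCAL)
        assert draw_matched_sets(pair, w, BootstrapConfig(),
                                 np.random.default_rng(0)) is None

    def test_weighted_draw_matches_target_distribution(self):
        A, B = (), (("LINE", "ns"),)
        pair = make_pair([(A, 700), (B, 300)], [(A, 500), (B, 1500)])
        w, _ = compute_sampling_weights(pair.test_pool, pair.reference_pool,
                                        FOCAL)
        rng = np.random.default_rng(3)
        cfg = BootstrapConfig(n_iterations=1)
        hits_A = 0
        total = 0
        for _ in range(50):
            _, r = draw_matched_sets(pair, w, cfg, rng)
            ids = set(p.gene_id for p in pair.reference_pool[:500])
            hits_A += sum(g in ids for g in r)
            total += len(r)
        assert abs(hits_A / total - 0.7) < 0.02


class TestIterationStatistics:
    def _expr(self, test_tpm, ref_tpm):
        genes = [f"t{i}" for i in range(len(test_tpm))] + \
                [f"r{i}" for i in range(len(ref_tpm))]
        values = pd.DataFrame({"s1": list(test_tpm) + list(ref_tpm)},
                              index=pd.Index(genes, name="gene_id"))
        meta = pd.DataFrame({"species": ["sp"], "tissue": ["brain"]},
                            index=pd.Index(["s1"], name="sample_id"))
        expr = ExpressionTable(values=values, sample_meta=meta)
        t_ids = [f"t{i}" for i in range(len(test_tpm))]
        r_ids = [f"r{i}" for i in range(len(ref_tpm))]
        return expr, t_ids, r_ids

    def test_median_difference_of_log2(self):
        # log2 values test {1,2,3}, ref {0,1,2} -> median diff 1.0
        expr, t, r = self._expr([2.0, 4.0, 8.0], [1.0, 2.0, 4.0])
        med, _ = iteration_statistics(t, r, expr, "s1", BootstrapConfig())
        assert med == pytest.approx(1.0)

    def test_zero_tpm_omitted_from_median_only(self):
        expr, t, r = self._expr([2.0, 4.0, 8.0, 0.0], [1.0, 2.0, 4.0, 0.0])
        med, prop = iteration_statistics(t, r, expr, "s1", BootstrapConfig())
        assert med == pytest.approx(1.0)  # zeros dropped from medians
        assert prop == pytest.approx(0.0)  # but kept in the proportions

    def test_proportion_expressed_difference(self):
        expr, t, r = self._expr([1.0] * 8 + [0.0] * 2, [1.0] * 6 + [0.0] * 4)
        _, prop = iteration_statistics(t, r, expr, "s1", BootstrapConfig())
        assert prop == pytest.approx(0.2)

    def test_identical_samples_give_zero(self):
        expr, t, r = self._expr([1.0, 5.0, 0.0], [1.0, 5.0, 0.0])
        med, prop = iteration_statistics(t, r, expr, "s1", BootstrapConfig())
        assert med == 0.0 and prop == 0.0

    def test_all_zero_set_gives_missing_median(self):
        expr, t, r = self._expr([0.0, 0.0], [1.0, 2.0])
        med, prop = iteration_statistics(t, r, expr, "s1", BootstrapConfig())
        assert np.isnan(med) and prop == pytest.approx(-1.0)


class TestCI:
    def test_quantile_oracle_on_known_sequence(self):
        lo, hi = ci_from_bootstrap(np.arange(1, 1001, dtype=float), 0.05, 1)
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_bonferroni_tail_levels(self):
        # alpha=0.05, m=24 -> quantiles at 0.0010417 and 0.9989583
        stats = np.arange(1, 100_001, dtype=float)
        lo, hi = ci_from_bootstrap(stats, 0.05, 24)
        a = 0.05 / 48
        assert lo == pytest.approx(np.quantile(stats, a))
        assert hi == pytest.approx(np.quantile(stats, 1 - a))
        assert a == pytest.approx(0.0010417, abs=1e-7)

    def test_constant_stats_degenerate_ci(self):
        lo, hi = ci_from_bootstrap(np.full(5000, 3.2), 0.05, 1)
        assert lo == hi == pytest.approx(3.2)

    def test_too_few_values_truncates_to_range_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            lo, hi = ci_from_bootstrap(np.arange(10.0), 0.05, 24)
        assert (lo, hi) == (0.0, 9.0)


class TestPValue:
    def test_all_positive_stats(self):
        p = pvalue_from_bootstrap(np.linspace(0.1, 5, 5000))
        assert p == pytest.approx(2 / 5001)

    def test_symmetric_stats_give_one(self):
        assert pvalue_from_bootstrap(np.array([-2.0, -1.0, 1.0, 2.0])) == 1.0

    def test_ties_at_zero_count_both_sides(self):
        stats = np.array([0.0] * 50 + [1.0] * 50)
        assert pvalue_from_bootstrap(stats) == 1.0

    def test_never_zero(self):
        assert pvalue_from_bootstrap(np.full(10, 7.0)) > 0


class TestBH:
    def test_worked_example(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(adjust_bh([1.0, 1.0]), [1.0, 1.0])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=1, max_size=10))
    @settings(max_examples=100, derandomize=True)
    def test_matches_exhaustive_definition(self, pvals):
        """Step-up definition: q_i = min over j with p_j >= p_i of p_j*n/rank_j,
        computed by brute force over the sorted vector."""
        n = len(pvals)
        order = np.argsort(pvals, kind="stable")
        q_sorted = np.empty(n)
        running = np.inf
        for rank in range(n, 0, -1):
            running = min(running, pvals[order[rank - 1]] * n / rank)
            q_sorted[rank - 1] = min(running, 1.0)
        expected = np.empty(n)
        expected[order] = q_sorted
        assert np.allclose(adjust_bh(pvals), expected)


class TestEffectConversion:
    @pytest.mark.parametrize("d,pct", [(1.0, 100.0), (0.0, 0.0),
                                       (-0.5, -29.289321881)])
    def test_log2_to_percent(self, d, pct):
        assert log2_change_to_percent(d) == pytest.approx(pct)


class TestRunBootstrap:
    def _setup(self, n=1500, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        pair = make_pair([((), n // 2), ((("LINE", "ns"),), n // 2)],
                         [((), n // 2), ((("LINE", "ns"),), n // 2)])
        ids = [p.gene_id for p in pair.test_pool + pair.reference_pool]
        log2 = rng.normal(2.0, 1.5, len(ids))
        log2[: pair.n_test] += shift
        values = pd.DataFrame({"s1": np.exp2(log2)},
                              index=pd.Index(ids, name="gene_id"))
        meta = pd.DataFrame({"species": ["sp"], "tissue": ["brain"]},
                            index=pd.Index(["s1"], name="sample_id"))
        return pair, ExpressionTable(values=values, sample_meta=meta)

    def test_deterministic_given_seed(self):
        pair, expr = self._setup()
        cfg = BootstrapConfig(n_iterations=200, seed=5)
        r1 = run_bootstrap(pair, expr, "s1", cfg)
        r2 = run_bootstrap(pair, expr, "s1", cfg)
        for stat in ("median_diff", "prop_diff"):
            assert r1.statistics[stat] == r2.statistics[stat]

    def test_clear_shift_detected(self):
        pair, expr = self._setup(shift=2.0, seed=1)
        res = run_bootstrap(pair, expr, "s1",
                            BootstrapConfig(n_iterations=1000, seed=2, m=24))
        s = res.statistics["median_diff"]
        assert s.ci_low > 0
        assert s.p_value == pytest.approx(2 / 1001)
        assert abs(s.estimate - 2.0) < 0.3

    def test_small_pool_skipped_without_statistics(self):
        pair = make_pair([((), 100)], [((), 5000)])
        _, expr = self._setup()
        ids = [p.gene_id for p in pair.test_pool + pair.reference_pool]
        values = pd.DataFrame({"s1": np.ones(len(ids))},
                              index=pd.Index(ids, name="gene_id"))
        expr = ExpressionTable(values=values, sample_meta=expr.sample_meta)
        res = run_bootstrap(pair, expr, "s1", BootstrapConfig())
        assert res.status == "skipped_small_pool"
        assert res.statistics == {}

    def test_pvalue_ci_consistency(self):
        """p < alpha/m iff the 1-alpha/m CI excludes zero (one rank slack)."""
        for seed in range(8):
            pair, expr = self._setup(seed=seed, shift=0.35)
            cfg = BootstrapConfig(n_iterations=2000, seed=seed, m=3)
            res = run_bootstrap(pair, expr, "s1", cfg)
            s = res.statistics["median_diff"]
            excludes = s.ci_low > 0 or s.ci_high < 0
            threshold = cfg.alpha / cfg.m
            slack = 2 * 2 / (cfg.n_iterations + 1)
            if s.p_value < threshold - slack:
                assert excludes
            if s.p_value > threshold + slack:
                assert not excludes

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="alpha"):
            BootstrapConfig(alpha=1.5)
        with pytest.raises(ConfigurationError, match="min_pool"):
            BootstrapConfig(min_pool=2000, n_genes_per_set=1000)
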