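"""Permutation nulls: draw contracts, enumeration oracles, BH, aux tests."""

import numpy as np
import pytest
from scipy import stats

from hicprox.contacts import HiCScoreMap
from hicprox.errors import DrawFailureError, ValidationError
from hicprox.permutation import (
    PermutationConfig,
    PermutationEngine,
    bh_adjust,
    group_test,
    individual_test,
    recurrence_correlation,
    tissue_comparison,
)
from hicprox.regions import (
    BinScheme,
    GenomeAssembly,
    GenomicRegion,
    MaskTrack,
    TranslocationPair,
)

from conftest import random_catalog


def _toy_engine(n1=6, n2=6, seed=0, mask_bins=()):
    """Small two-chromosome engine with random scores; optionally masked."""
    rng = np.random.default_rng(seed)
    asm = GenomeAssembly(("chr1", "chr2"), (n1 * 1_000_000, n2 * 1_000_000))
    scheme = BinScheme(asm, 1_000_000)
    block = rng.normal(size=(n1, n2))
    mask = MaskTrack(scheme)
    for chrom, b in mask_bins:
        mask.add(scheme.global_index(chrom, b * 1_000_000), "no_coverage")
        if chrom == "chr1":
            block[b, :] = np.nan
        else:
            block[:, b] = np.nan
    smap = HiCScoreMap(scheme, {("chr1", "chr2"): block}, 1.0, mask)
    return PermutationEngine(smap, mask), scheme, block


def _pair(scheme, a, b):
    bs = scheme.bin_size
    return TranslocationPair(
        GenomicRegion("chr1", a[0] * bs, a[1] * bs),
        GenomicRegion("chr2", b[0] * bs, b[1] * bs),
    )


class TestDrawContracts:
    def test_method1_preserves_chromosomes_and_widths(self, null_setup):
        engine = null_setup["engine"]
        scheme = null_setup["ds"].scheme
        rng = np.random.default_rng(0)
        pair = random_catalog(engine, scheme, 1, rng)[0]
        cfg = PermutationConfig(method=1, n_perms=1)
        wa = len(scheme.region_bins(pair.region_a))
        wb = len(scheme.region_bins(pair.region_b))
        for _ in range(200):
            perm = engine.draw_permuted_pair(pair, cfg, rng)
            assert {perm.region_a.chrom, perm.region_b.chrom} == {
                pair.region_a.chrom, pair.region_b.chrom
            }
            widths = {
                perm.region_a.chrom: len(scheme.region_bins(perm.region_a)),
                perm.region_b.chrom: len(scheme.region_bins(perm.region_b)),
            }
            assert widths[pair.region_a.chrom] == wa
            assert widths[pair.region_b.chrom] == wb

    def test_method3_partner_leaves_fixed_chromosome(self, null_setup):
        engine = null_setup["engine"]
        scheme = null_setup["ds"].scheme
        rng = np.random.default_rng(1)
        pair = random_catalog(engine, scheme, 1, rng)[0]
        cfg = PermutationConfig(method=3, n_perms=1)
        for _ in range(200):
            perm = engine.draw_permuted_pair(pair, cfg, rng)
            assert perm.region_a.chrom != perm.region_b.chrom

    def test_method4_partner_comes_from_pool_off_fixed_chrom(self, null_setup):
        engine = null_setup["engine"]
        scheme = null_setup["ds"].scheme
        rng = np.random.default_rng(2)
        pairs = random_catalog(engine, scheme, 10, rng)
        pool_regions = {
            (r.chrom, r.start, r.end)
            for p in pairs for r in (p.region_a, p.region_b)
        }
        originals = {
            (r.chrom, r.start, r.end)
            for r in (pairs[0].region_a, pairs[0].region_b)
        }
        cfg = PermutationConfig(method=4, n_perms=1)
        for _ in range(100):
            perm = engine.draw_permuted_pair(pairs[0], cfg, rng, partner_pool=pairs)
            regions = {
                (r.chrom, r.start, r.end)
                for r in (perm.region_a, perm.region_b)
            }
            moved = regions - originals
            assert all(r in pool_regions for r in moved)

    def test_compartment_control_preserves_sign(self, null_setup):
        engine = null_setup["engine"]
        scheme = null_setup["ds"].scheme
        rng = np.random.default_rng(3)
        pair = random_catalog(engine, scheme, 1, rng)[0]
        cfg = PermutationConfig(method=1, n_perms=1, compartment_control=True)
        signs = {
            r.chrom: engine.region_sign(r)
            for r in (pair.region_a, pair.region_b)
        }
        for _ in range(100):
            perm = engine.draw_permuted_pair(pair, cfg, rng)
            for r in (perm.region_a, perm.region_b):
                assert engine.region_sign(r) == signs[r.chrom]

    def test_masked_block_placement_matches_enumeration_oracle(self):
        # 60% of chr1 masked contiguously: empirical placement frequencies
        # must match uniform-over-valid-placements (3 binomial SE, 10k draws)
        n1 = 10
        masked = [("chr1", b) for b in range(4, 10)]  # 6 of 10 bins
        engine, scheme, _ = _toy_engine(n1=n1, n2=10, mask_bins=masked)
        width, thr = 2, 0.5
        valid = [
            s for s in range(n1 - width + 1)
            if sum(4 <= b < 10 for b in range(s, s + width)) < thr * width
        ]
        assert list(engine.valid_starts("chr1", width, thr)) == valid
        pair = _pair(scheme, (0, width), (0, 2))
        cfg = PermutationConfig(method=1, n_perms=1)
        rng = np.random.default_rng(7)
        draws = 10_000
        c1, s1, w1, *_ = engine._draw_placements(pair, cfg, draws, rng)
        freq = np.bincount(s1, minlength=n1)[valid] / draws
        p = 1 / len(valid)
        se = np.sqrt(p * (1 - p) / draws)
        assert np.all(np.abs(freq - p) <= 3 * se)

    def test_draw_failure_when_no_valid_placement(self):
        engine, scheme, _ = _toy_engine(
            mask_bins=[("chr1", b) for b in range(6)]
        )
        pair = _pair(scheme, (0, 2), (0, 2))
        with pytest.raises(DrawFailureError):
            engine.draw_permuted_pair(
                pair, PermutationConfig(method=1), np.random.default_rng(0)
            )


class TestEnumerationOracles:
    """Monte-Carlo p-values vs exact enumeration on fully enumerable toys."""

    def test_individual_p_matches_exact_enumeration(self):
        engine, scheme, block = _toy_engine(seed=10)
        wa = wb = 2
        pair = _pair(scheme, (1, 3), (2, 4))
        obs = engine.pair_statistic(pair)
        # exact: all placements of both regions (method 1)
        stats_all = [
            float(engine.block_means("chr1", sa, wa, "chr2", sb, wb))
            for sa in range(5) for sb in range(5)
        ]
        p_exact = np.mean([s >= obs for s in stats_all])
        n = 10_000
        cfg = PermutationConfig(method=1, n_perms=n, rng_seed=5)
        res = individual_test([pair, _pair(scheme, (0, 2), (0, 2))], engine, cfg)
        p_mc = res.p_values[0]
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(p_mc - (n * p_exact + 1) / (n + 1)) <= 3 * se + 1e-12

    def test_group_p_matches_exact_enumeration(self):
        engine, scheme, block = _toy_engine(seed=11)
        pairs = [_pair(scheme, (1, 3), (2, 4)), _pair(scheme, (0, 2), (3, 5))]
        cfg = PermutationConfig(method=1, n_perms=10_000, rng_seed=6)
        res = group_test(pairs, engine, cfg)
        # exact null: every combination of placements of both pairs
        per_pair_stats = []
        for wa, wb in [(2, 2), (2, 2)]:
            per_pair_stats.append([
                float(engine.block_means("chr1", sa, wa, "chr2", sb, wb))
                for sa in range(5) for sb in range(5)
            ])
        means = [
            (s1 + s2) / 2
            for s1 in per_pair_stats[0] for s2 in per_pair_stats[1]
        ]
        p_exact = np.mean([m >= res.observed_mean for m in means])
        n = cfg.n_perms
        se = np.sqrt(p_exact * (1 - p_exact) / n)
        assert abs(res.p_value - (n * p_exact + 1) / (n + 1)) <= 3 * se + 1e-12


class TestGroupAndIndividual:
    def test_boundary_p_is_one_over_n_plus_one(self, planted_setup):
        # make the observed unbeatable by shifting scores of the true pairs
        engine, scheme = planted_setup["engine"], planted_setup["ds"].scheme
        pairs = [
            p for p, l in zip(
                planted_setup["ds"].catalog_pairs(),
                planted_setup["ds"].truth.catalog_labels,
            ) if l == "true"
        ]
        cfg = PermutationConfig(method=1, n_perms=1000, rng_seed=8)
        res = group_test(pairs, engine, cfg)
        if res.observed_mean > res.null_means.max():
            assert res.p_value == pytest.approx(1 / 1001)
            assert res.format_p() == "<0.001"

    def test_determinism_same_seed_bit_identical(self, null_setup):
        engine, scheme = null_setup["engine"], null_setup["ds"].scheme
        pairs = random_catalog(
            engine, scheme, 5, np.random.default_rng(9)
        )
        cfg = PermutationConfig(method=2, n_perms=200, rng_seed=42)
        a = group_test(pairs, engine, cfg)
        b = group_test(pairs, engine, cfg)
        np.testing.assert_array_equal(a.null_means, b.null_means)
        assert a.p_value == b.p_value

    def test_planted_hotspot_pair_detected_individually(self, planted_setup):
        ds = planted_setup["ds"]
        engine = planted_setup["engine"]
        pairs = ds.catalog_pairs()
        labels = ds.truth.catalog_labels
        cfg = PermutationConfig(method=1, n_perms=500, rng_seed=13)
        res = individual_test(pairs, engine, cfg)
        true_p = res.p_values[np.array(labels) == "true"]
        null_p = res.p_values[np.array(labels) == "null"]
        # hotspot pairs rank far below null pairs
        assert np.median(true_p) < 0.1 < np.median(null_p)

    def test_group_power_on_planted_catalog(self, planted_setup):
        ds = planted_setup["ds"]
        pairs = [
            p for p, l in zip(ds.catalog_pairs(), ds.truth.catalog_labels)
            if l == "true"
        ]
        cfg = PermutationConfig(method=1, n_perms=1000, rng_seed=14)
        res = group_test(pairs, planted_setup["engine"], cfg)
        assert res.p_value <= 0.01
        assert res.t_test_p < 0.05 and res.rank_sum_p < 0.05


class TestBH:
    def test_hand_examples(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust([0.005, 0.5]), [0.01, 0.5])
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_against_statsmodels_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(15)
        for _ in range(20):
            p = rng.random(rng.integers(1, 50)).clip(1e-9, 1.0)
            q = bh_adjust(p)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_ref)

    def test_monotone_in_sorted_order_and_bounded(self):
        rng = np.random.default_rng(16)
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0) and np.all(q >= p * 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestTissueComparison:
    def test_identical_groups_give_p_one(self):
        res = tissue_comparison([1, 2, 3], [1, 2, 3])
        assert res["rank_sum_p"] == pytest.approx(1.0)

    def test_separated_groups_near_minimal_p(self):
        res = tissue_comparison([1, 2, 3], [101, 102, 103])
        # exact two-sided enumeration floor for n=3,3 is 0.1
        assert 0 < res["rank_sum_p"] <= 0.1
        assert res["median_1"] == 2 and res["median_2"] == 102

    def test_null_relabeling_calibration(self):
        rng = np.random.default_rng(17)
        pooled = rng.normal(size=40)
        ps = []
        for _ in range(500):
            perm = rng.permutation(pooled)
            ps.append(tissue_comparison(perm[:20], perm[20:])["rank_sum_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValidationError):
            tissue_comparison([1.0, 1.0], [1.0, 1.0])


class TestRecurrenceCorrelation:
    def test_perfect_alignment_and_antialignment(self):
        res = recurrence_correlation([1, 2, 3], [0.1, 0.2, 0.3])
        assert res["rho_score"] == pytest.approx(1.0)
        res = recurrence_correlation([1, 2, 3], [3.0, 2.0, 1.0])
        assert res["rho_score"] == pytest.approx(-1.0)

    def test_independent_counts_give_small_rho(self):
        rng = np.random.default_rng(18)
        hits = 0
        for _ in range(40):
            counts = rng.integers(1, 30, 200)
            scores = rng.normal(size=200)
            res = recurrence_correlation(counts, scores)
            hits += abs(res["rho_score"]) < 0.2
        assert hits >= 38  # ~95% of seeds

    def test_slope_t_p_reported_with_pvalues(self):
        rng = np.random.default_rng(19)
        counts = rng.integers(1, 30, 50)
        res = recurrence_correlation(
            counts, rng.normal(size=50), rng.random(50)
        )
        assert 0 < res["slope_t_p_pvalue_vs_count"] <= 1

    def test_constant_inputs_rejected(self):
        with pytest.raises(ValidationError):
            recurrence_correlation([2, 2, 2], [0.1, 0.2, 0.3])


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"method": 5}, {"n_perms": 0}, {"validity_threshold": 0.0},
        {"method": 4, "compartment_control": True},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            PermutationConfig(**kwargs)
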