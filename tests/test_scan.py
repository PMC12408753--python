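"""Percentile binning, the Mann-Whitney oracle equivalences, BH step-up,
bootstrap determinism and the fast-path/literal-loop equivalence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdenscan import DataError, ScanConfig, assign_bins, bh_fdr, bootstrap_gene, extreme_groups, mann_whitney_u
from burdenscan.scan import _batch_mwu, bin_sizes, _gene_rng
from oracles import bh_stepup_oracle, mwu_exact_oracle


def test_bin_partition_properties():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n_bins = int(rng.integers(2, 120))
        n = int(rng.integers(n_bins, n_bins * 30))
        scores = rng.random(n)
        bins = assign_bins(scores, rng.random(n), n_bins)
        counts = np.bincount(bins, minlength=n_bins)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1
        k_low, k_high = bin_sizes(n, n_bins)
        assert counts[0] == k_low and counts[-1] == k_high


def test_exact_division_gives_equal_bins():
    bins = assign_bins(np.arange(200.0), np.random.default_rng(0).random(200), 100)
    assert (np.bincount(bins) == 2).all()


def test_distinct_scores_ignore_tie_break():
    rng = np.random.default_rng(1)
    scores = rng.permutation(300).astype(float)
    b1 = assign_bins(scores, rng.random(300), 50)
    b2 = assign_bins(scores, rng.random(300), 50)
    assert np.array_equal(b1, b2)


def test_small_example_matches_sort_oracle():
    scores = np.array([0.0, 0.0, 0.0, 1.0, 2.0])
    keys = np.array([0.3, 0.1, 0.2, 0.9, 0.4])
    bins = assign_bins(scores, keys, 2)
    # sorted by (score, key): indices 1,2,0,3,4 -> first 2 of 5 in bin 0
    order = sorted(range(5), key=lambda i: (scores[i], keys[i]))
    expected = np.empty(5, int)
    for pos, i in enumerate(order):
        expected[i] = (pos * 2) // 5
    assert np.array_equal(bins, expected)
    # floor(i*2/5) puts the first 3 sorted entries (ceil(5/2)) in bin 0
    assert set(np.flatnonzero(bins == 0)) == {0, 1, 2}


def test_stratum_smaller_than_bins_raises():
    with pytest.raises(DataError):
        assign_bins(np.arange(5.0), np.arange(5.0), 10)


def test_extreme_groups_zero_exclusion():
    scores = np.zeros(10)
    bins = assign_bins(scores, np.random.default_rng(0).random(10), 5)
    low, high = extreme_groups(bins, scores, 5)
    assert len(high) == 0 and len(low) == 2
    # mixed top bin keeps only non-zero members
    scores2 = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1.0, 0])
    bins2 = assign_bins(scores2, np.arange(10.0), 5)
    low2, high2 = extreme_groups(bins2, scores2, 5)
    assert list(high2) == [8]
    # dense gene keeps the whole top bin
    scores3 = np.arange(1.0, 11.0)
    bins3 = assign_bins(scores3, np.arange(10.0), 5)
    _, high3 = extreme_groups(bins3, scores3, 5)
    assert len(high3) == 2


def test_mwu_identical_multisets():
    x = np.array([1.0, 2.0, 3.0])
    assert mann_whitney_u(x, x) == pytest.approx(1.0, abs=1e-9)


def test_mwu_fixed_exact_example():
    assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)


def test_mwu_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    for _ in range(40):
        n1, n2 = rng.integers(2, 8, 2)
        x = rng.normal(size=int(n1))
        y = rng.normal(size=int(n2))
        assert mann_whitney_u(x, y) == pytest.approx(mwu_exact_oracle(x, y), abs=1e-10)


def test_batch_mwu_matches_scipy_asymptotic():
    rng = np.random.default_rng(4)
    for with_ties in (False, True):
        x = rng.normal(size=(50, 12))
        y = rng.normal(size=(50, 20))
        if with_ties:
            x = np.round(x, 1)
            y = np.round(y, 1)
        ps = _batch_mwu(x, y)
        for i in range(50):
            ref = stats.mannwhitneyu(x[i], y[i], alternative="two-sided",
                                     method="asymptotic").pvalue
            assert ps[i] == pytest.approx(ref, abs=1e-12)


def test_bh_single_and_stepup_example():
    assert bh_fdr([0.03])[0] == pytest.approx(0.03)
    adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04)


def test_bh_matches_stepup_oracle():
    rng = np.random.default_rng(5)
    for _ in range(30):
        p = rng.random(int(rng.integers(1, 60)))
        assert np.allclose(bh_fdr(p), bh_stepup_oracle(p), atol=0, rtol=1e-12)


def test_bh_rejects_invalid_p():
    with pytest.raises(DataError):
        bh_fdr([0.5, 1.5])


def _sparse_gene(n, n_carriers, seed):
    rng = np.random.default_rng(seed)
    scores = np.zeros(n)
    idx = rng.choice(n, n_carriers, replace=False)
    scores[idx] = rng.uniform(0.5, 5.0, n_carriers)
    pheno = rng.normal(3.7, 0.8, n)
    return scores, pheno


def test_bootstrap_same_seed_is_identical():
    scores, pheno = _sparse_gene(500, 30, 0)
    cfg = ScanConfig(n_bins=50, n_iterations=50, rng_seed=0)
    r1 = bootstrap_gene(scores, pheno, cfg, np.random.default_rng(9))
    r2 = bootstrap_gene(scores, pheno, cfg, np.random.default_rng(9))
    assert r1.mean_p == r2.mean_p and r1.sd_p == r2.sd_p


def test_tie_free_scores_have_zero_sd_and_seed_invariance():
    rng = np.random.default_rng(6)
    scores = rng.permutation(400).astype(float) + 1.0
    pheno = rng.normal(size=400)
    cfg = ScanConfig(n_bins=100, n_iterations=200, rng_seed=0)
    r1 = bootstrap_gene(scores, pheno, cfg, np.random.default_rng(1))
    r2 = bootstrap_gene(scores, pheno, cfg, np.random.default_rng(2))
    assert r1.sd_p == 0.0
    assert r1.mean_p == r2.mean_p
    # and the shortcut equals the literal loop
    r3 = bootstrap_gene(scores, pheno, cfg, np.random.default_rng(3), literal=True)
    assert r3.mean_p == pytest.approx(r1.mean_p, abs=1e-12)
    assert r3.sd_p == pytest.approx(0.0, abs=1e-15)


@pytest.mark.parametrize("n,n_bins,n_carriers", [(60, 10, 9), (300, 10, 25), (400, 100, 50)])
def test_fast_path_equals_literal_loop(n, n_bins, n_carriers):
    # same RNG stream -> bitwise-identical group selection, identical summary
    scores, pheno = _sparse_gene(n, n_carriers, seed=n)
    cfg = ScanConfig(n_bins=n_bins, n_iterations=40, rng_seed=0)
    fast = bootstrap_gene(scores, pheno, cfg, np.random.default_rng(12))
    lit = bootstrap_gene(scores, pheno, cfg, np.random.default_rng(12), literal=True)
    assert fast.n_valid_iterations == lit.n_valid_iterations
    assert fast.mean_p == pytest.approx(lit.mean_p, abs=1e-12)
    assert fast.sd_p == pytest.approx(lit.sd_p, abs=1e-12)
    assert (fast.n_low_group, fast.n_high_group) == (lit.n_low_group, lit.n_high_group)


def test_all_zero_gene_is_untestable():
    cfg = ScanConfig(n_bins=10, n_iterations=20)
    res = bootstrap_gene(np.zeros(100), np.random.default_rng(0).normal(size=100),
                         cfg, np.random.default_rng(0))
    assert res.n_valid_iterations == 0
    assert np.isnan(res.mean_p)


def test_planted_shift_detected():
    rng = np.random.default_rng(8)
    n = 2000
    scores = np.zeros(n)
    carriers = rng.choice(n, 25, replace=False)
    scores[carriers] = rng.uniform(1, 3, 25)
    pheno = rng.normal(3.7, 0.8, n)
    pheno[carriers] += 1.5
    cfg = ScanConfig(n_bins=100, n_iterations=100, rng_seed=0)
    res = bootstrap_gene(scores, pheno, cfg, np.random.default_rng(0))
    assert res.mean_p < 1e-4


def test_gene_rng_is_order_independent():
    a = _gene_rng(3, "GENE1").random(4)
    b = _gene_rng(3, "GENE2").random(4)
    a2 = _gene_rng(3, "GENE1").random(4)
    assert np.array_equal(a, a2)
    assert not np.array_equal(a, b)
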