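"""aHWE tests: EM estimators against brute-force oracles, LR properties."""

import numpy as np
import pytest

from octohwe import (
    allele_equilibrium_freqs,
    allele_lr_test,
    collapse_dosage,
    em_allele_freq,
    em_gamete_freqs,
    equilibrium_genotype_freqs,
    equilibrium_proxy,
    gamete_lr_test,
    recursive_test,
)
from oracles import best_allele_freq, grid_max_gamete_loglik

DEMO_COUNTS = np.array([8, 8, 4, 8, 16, 8, 12, 8, 8])  # ascending dosage, N=80


def random_counts(rng, n_classes=9, n_min=30, n_max=400):
    freqs = rng.dirichlet(np.ones(n_classes))
    return rng.multinomial(rng.integers(n_min, n_max), freqs)


# ---------------------------------------------------------------- equilibrium maps

def test_equilibrium_genotype_freqs_is_gamete_product():
    assert np.allclose(equilibrium_genotype_freqs([0, 0, 0, 0, 1]),
                       [0, 0, 0, 0, 0, 0, 0, 0, 1])
    Q = equilibrium_genotype_freqs(np.full(5, 0.2))
    # balanced heterozygote: 2*g4*g0 + 2*g3*g1 + g2^2
    assert Q[4] == pytest.approx(2 * 0.04 + 2 * 0.04 + 0.04, abs=1e-15)
    assert Q.sum() == pytest.approx(1.0, abs=1e-12)


def test_allele_equilibrium_freqs_binomial_identity():
    assert np.allclose(allele_equilibrium_freqs(0.5), [1 / 256, 127 / 128, 1 / 256])
    assert np.allclose(allele_equilibrium_freqs(1.0), [1, 0, 0])
    p, q = 0.9, 0.1
    explicit = sum(
        c * p**d * q ** (8 - d)
        for c, d in zip([8, 28, 56, 70, 56, 28, 8], range(7, 0, -1))
    )
    assert allele_equilibrium_freqs(p)[1] == pytest.approx(explicit, abs=1e-14)


def test_collapse_dosage():
    assert list(collapse_dosage([10, 1, 1, 1, 1, 1, 1, 1, 10])) == [10, 7, 10]
    n = np.zeros(9, dtype=int)
    n[0] = 5
    assert list(collapse_dosage(n)) == [0, 0, 5]
    c = np.arange(1, 10)
    assert collapse_dosage(c).sum() == c.sum()


# ---------------------------------------------------------------- gamete EM

def test_gamete_em_recovers_exact_equilibrium_counts():
    """Counts exactly proportional to an interior equilibrium recover its gametes."""
    g_true = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
    counts = np.round(equilibrium_genotype_freqs(g_true) * 10_000).astype(int)
    est = em_gamete_freqs(counts)
    assert est.converged
    assert np.abs(est.probs - g_true).max() < 1e-6


def test_gamete_em_boundary():
    counts = np.zeros(9, dtype=int)
    counts[0] = 40
    est = em_gamete_freqs(counts)
    assert np.allclose(est.probs, [1, 0, 0, 0, 0], atol=1e-9)


def test_gamete_em_dominates_grid_search(rng):
    """EM log-likelihood is never below the best 0.02-resolution grid point."""
    for _ in range(30):
        counts = random_counts(rng)
        est = em_gamete_freqs(counts)
        assert est.loglik >= grid_max_gamete_loglik(counts) - 1e-6


def test_gamete_em_loglik_monotone(rng):
    for _ in range(20):
        est = em_gamete_freqs(random_counts(rng))
        assert np.all(np.diff(est.loglik_path) >= -1e-9)


def test_gamete_lr_zero_at_equilibrium_and_symmetry(rng):
    g = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
    counts = np.round(equilibrium_genotype_freqs(g) * 10_000).astype(int)
    res = gamete_lr_test(counts)
    assert res.df == 4
    assert res.statistic == pytest.approx(0.0, abs=1e-6)
    assert res.pvalue == pytest.approx(1.0, abs=1e-6)
    for _ in range(10):
        counts = random_counts(rng)
        a = gamete_lr_test(counts)
        b = gamete_lr_test(counts[::-1])
        assert a.statistic >= 0.0
        assert a.statistic == pytest.approx(b.statistic, abs=1e-6)


def test_gamete_lr_large_for_disjoint_homozygotes():
    """Mass on both homozygotes with no heterozygotes cannot fit any gamete simplex."""
    counts = np.zeros(9, dtype=int)
    counts[0] = counts[8] = 50
    res = gamete_lr_test(counts)
    assert res.statistic > 50
    assert res.pvalue < 1e-10
    # the EM fit is still no worse than the grid oracle at this hard boundary case
    assert res.nuisance.loglik >= grid_max_gamete_loglik(counts) - 1e-6


# ---------------------------------------------------------------- allele EM

def test_allele_em_boundaries_and_symmetry():
    assert em_allele_freq([40, 0, 0]).p == 1.0
    assert em_allele_freq([0, 0, 40]).p == 0.0
    assert em_allele_freq([13, 50, 13]).p == pytest.approx(0.5, abs=1e-9)


def test_allele_em_matches_one_dimensional_oracle(rng):
    cases = [np.array([30, 60, 10])] + [random_counts(rng, n_classes=3)
                                        for _ in range(30)]
    for counts in cases:
        if np.count_nonzero(counts) <= 1:
            continue
        est = em_allele_freq(counts)
        assert abs(est.p - best_allele_freq(counts)) < 1e-6


def test_allele_em_loglik_monotone(rng):
    for _ in range(20):
        est = em_allele_freq(random_counts(rng, n_classes=3))
        assert np.all(np.diff(est.loglik_path) >= -1e-9)


def test_allele_lr_zero_at_equilibrium_and_symmetry():
    # (10, 2540, 10) sits exactly at the p=0.5 equilibrium (1, 254, 1)/256
    counts = np.round(allele_equilibrium_freqs(0.5) * 2560).astype(int)
    assert list(counts) == [10, 2540, 10]
    res = allele_lr_test(counts)
    assert res.df == 1
    assert res.statistic == pytest.approx(0.0, abs=1e-6)
    a = allele_lr_test([30, 60, 10])
    b = allele_lr_test([10, 60, 30])
    assert a.statistic == pytest.approx(b.statistic, abs=1e-9)


def test_allele_lr_large_without_heterozygotes():
    """Two homozygote classes and no heterozygotes is far off equilibrium."""
    res = allele_lr_test([50, 0, 50])
    p_star = best_allele_freq([50, 0, 50])
    from oracles import allele_loglik

    saturated = 50 * np.log(0.5) + 50 * np.log(0.5)
    expected = -2 * (allele_loglik(p_star, [50, 0, 50]) - saturated)
    assert res.statistic == pytest.approx(expected, rel=1e-6)
    assert res.statistic > 20


def test_allele_lr_degenerate_single_class():
    res = allele_lr_test([0, 40, 0])
    assert res.statistic == 0.0
    assert res.pvalue == 1.0


# ---------------------------------------------------------------- recursive test

def test_recursive_test_zero_at_its_own_fixed_point(demo_start):
    """Counts drawn from an equilibrium-proxy vector give a near-zero statistic."""
    proxy = equilibrium_proxy(demo_start, 0.1)
    counts = np.round(proxy * 1_000_000).astype(int)
    res = recursive_test(counts, alpha=0.1)
    assert res.df == 8
    assert res.statistic < 0.01
    assert res.pvalue > 0.999


def test_recursive_test_monomorphic_counts():
    counts = np.zeros(9, dtype=int)
    counts[8] = 77
    res = recursive_test(counts, alpha=0.2)
    assert res.statistic == 0.0
    assert res.pvalue == 1.0


def test_recursive_test_against_direct_arithmetic(demo_start):
    """Statistic equals the chi-square formula applied to an independently
    iterated (gamete-pool path) 15-generation proxy."""
    from octohwe import next_generation_pool

    res = recursive_test(DEMO_COUNTS, alpha=0.0)
    P = DEMO_COUNTS / DEMO_COUNTS.sum()
    Pbar = P.copy()
    for _ in range(15):
        Pbar = next_generation_pool(Pbar, 0.0)
    expected = DEMO_COUNTS.sum() * np.sum((P - Pbar) ** 2 / Pbar)
    assert res.statistic == pytest.approx(expected, rel=1e-10)
    assert res.statistic > 0.0


def test_count_validation():
    with pytest.raises(ValueError):
        recursive_test(np.zeros(9, dtype=int))
    with pytest.raises(ValueError):
        gamete_lr_test([1, 2, 3])  # wrong length
    with pytest.raises(ValueError):
        allele_lr_test([-1, 2, 3])
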