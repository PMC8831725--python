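"""Independent oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: gamete
distributions are obtained by exhaustive enumeration of meiotic outcomes in
exact rational arithmetic, and maximum-likelihood estimates by brute-force
search.  They exist to cross-check the implementation, not to share code with
it.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy.optimize import minimize_scalar


def enum_diploid_gamete(dosage: int, alpha: Fraction) -> list[Fraction]:
    """Diploid sub-gamete distribution by exhaustive enumeration.

    Chromosomes are ``dosage`` copies of A and ``8 - dosage`` copies of a.
    With probability alpha choose one chromosome uniformly and emit its sister
    chromatid pair; otherwise choose one of the 28 unordered pairs of distinct
    chromosomes uniformly.
    """
    alleles = [1] * dosage + [0] * (8 - dosage)
    probs = [Fraction(0)] * 3
    for c in alleles:  # double reduction: sister chromatids of one chromosome
        probs[2 * c] += alpha * Fraction(1, 8)
    for c1, c2 in itertools.combinations(alleles, 2):
        probs[c1 + c2] += (1 - alpha) * Fraction(1, 28)
    return probs


def enum_tetraploid_gamete(dosage: int, alpha: Fraction) -> list[Fraction]:
    """Tetraploid gamete distribution: rational self-convolution of the enumeration."""
    d = enum_diploid_gamete(dosage, alpha)
    out = [Fraction(0)] * 5
    for i, pi in enumerate(d):
        for j, pj in enumerate(d):
            out[i + j] += pi * pj
    return out


def enum_gamete_table(alpha: Fraction) -> list[list[Fraction]]:
    """9x5 rational gamete table, rows by ascending genotype dosage."""
    return [enum_tetraploid_gamete(i, alpha) for i in range(9)]


def simplex_grid(n_parts: int, resolution: int) -> np.ndarray:
    """All compositions of ``resolution`` into ``n_parts`` parts, as probabilities."""
    combos = itertools.combinations(range(resolution + n_parts - 1), n_parts - 1)
    grid = np.array(
        [np.diff([-1, *c, resolution + n_parts - 1]) - 1 for c in combos],
        dtype=float,
    )
    return grid / resolution


def grid_max_gamete_loglik(counts, resolution: int = 50) -> float:
    """Best equilibrium log-likelihood over a simplex grid of gamete frequencies."""
    G = simplex_grid(5, resolution)
    Q = np.zeros((G.shape[0], 9))
    for d1 in range(5):
        for d2 in range(5):
            Q[:, d1 + d2] += G[:, d1] * G[:, d2]
    logQ = np.log(np.clip(Q, 1e-300, None))
    ll = logQ @ np.asarray(counts, dtype=float)
    return float(ll.max())


def grid_max_gamete_loglik_many(count_matrix, resolution: int = 50) -> np.ndarray:
    """Vectorized :func:`grid_max_gamete_loglik` for an (m, 9) count matrix."""
    G = simplex_grid(5, resolution)
    Q = np.zeros((G.shape[0], 9))
    for d1 in range(5):
        for d2 in range(5):
            Q[:, d1 + d2] += G[:, d1] * G[:, d2]
    logQ = np.log(np.clip(Q, 1e-300, None))
    ll = logQ @ np.asarray(count_matrix, dtype=float).T  # (grid, m)
    return ll.max(axis=0)


def allele_loglik(p: float, counts3) -> float:
    n_homA, n_het, n_homa = counts3
    q = 1.0 - p
    het = max(1.0 - p**8 - q**8, 1e-300)
    terms = 0.0
    if n_homA:
        terms += n_homA * 8 * math.log(max(p, 1e-300))
    if n_het:
        terms += n_het * math.log(het)
    if n_homa:
        terms += n_homa * 8 * math.log(max(q, 1e-300))
    return terms


def best_allele_freq(counts3) -> float:
    """1-D MLE of the allele frequency: coarse grid then bounded refinement."""
    ps = np.linspace(1e-9, 1 - 1e-9, 4001)
    lls = [allele_loglik(p, counts3) for p in ps]
    i = int(np.argmax(lls))
    lo, hi = ps[max(i - 1, 0)], ps[min(i + 1, len(ps) - 1)]
    res = minimize_scalar(lambda p: -allele_loglik(p, counts3),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)
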