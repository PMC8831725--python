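"""Tests of asymptotic Hardy-Weinberg equilibrium (aHWE) in octoploids.

Three tests are provided, matching the three levels at which per-SNP genotype
data may resolve:

* :func:`recursive_test` — dosage-known counts; Pearson chi-square of the
  observed genotype frequencies against their own 15-generation random-mating
  image (the equilibrium proxy), 8 degrees of freedom.
* :func:`gamete_lr_test` — dosage-known counts; likelihood-ratio test of the
  5-parameter gamete-product equilibrium manifold against the saturated
  9-class multinomial, 4 degrees of freedom.  The gamete frequencies under the
  null are fitted with an EM algorithm (:func:`em_gamete_freqs`).
* :func:`allele_lr_test` — dosage-unknown counts (homozygote-A / mixed
  heterozygote / homozygote-a); likelihood-ratio test of the 1-parameter
  binomial-power equilibrium against the saturated trinomial, 1 degree of
  freedom, with the allele frequency fitted by EM (:func:`em_allele_freq`).

Log-likelihoods drop the multinomial coefficient (a constant shared by both
hypotheses) and use the convention 0*log(0) = 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .transmission import equilibrium_proxy

__all__ = [
    "TestResult",
    "GameteFreqEstimate",
    "AlleleFreqEstimate",
    "validate_counts",
    "collapse_dosage",
    "multinomial_loglik",
    "equilibrium_genotype_freqs",
    "allele_equilibrium_freqs",
    "em_gamete_freqs",
    "em_allele_freq",
    "recursive_test",
    "gamete_lr_test",
    "allele_lr_test",
]

_EPS = 1e-12  # probability floor inside logs during iteration


@dataclass(frozen=True)
class TestResult:
    """Outcome of an aHWE test."""

    method: str  # 'recursive' | 'gamete' | 'allele'
    statistic: float
    df: int
    pvalue: float
    nuisance: object = None  # estimate object or proxy vector, method-dependent


@dataclass(frozen=True)
class GameteFreqEstimate:
    """MLE of the five tetraploid-gamete frequencies under equilibrium."""

    probs: np.ndarray  # 5-vector, ascending gamete dosage
    loglik: float
    iterations: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class AlleleFreqEstimate:
    """MLE of the A-allele frequency under equilibrium (dosage-unknown data)."""

    p: float
    loglik: float
    iterations: int
    converged: bool
    loglik_path: np.ndarray = field(repr=False, default=None)

    @property
    def q(self) -> float:
        return 1.0 - self.p


def validate_counts(counts, n_classes: int = 9) -> np.ndarray:
    """Validate a vector of nonnegative integer genotype counts."""
    N = np.asarray(counts, dtype=np.float64)
    if N.shape != (n_classes,):
        raise ValueError(f"expected {n_classes} genotype counts, got shape {N.shape}")
    if np.any(N < 0) or not np.allclose(N, np.round(N)):
        raise ValueError("counts must be nonnegative integers")
    N = np.round(N).astype(np.int64)
    if N.sum() < 1:
        raise ValueError("total count must be >= 1")
    return N


def collapse_dosage(counts) -> np.ndarray:
    """Collapse 9-class dosage-known counts to (n_homA, n_het, n_homa).

    The seven heterozygous dosage classes are indistinguishable for
    dosage-unknown markers and pool into a single class.
    """
    N = validate_counts(counts)
    return np.array([N[8], N[1:8].sum(), N[0]], dtype=np.int64)


def multinomial_loglik(counts, probs) -> float:
    """Multinomial log-likelihood without the constant term; 0*log(0) = 0."""
    N = np.asarray(counts, dtype=float)
    P = np.asarray(probs, dtype=float)
    mask = N > 0
    return float(N[mask] @ np.log(np.clip(P[mask], _EPS, None)))


def equilibrium_genotype_freqs(gametes) -> np.ndarray:
    """Genotype frequencies under equilibrium for given gamete frequencies.

    Random union of two gametes: the 9-class genotype distribution is the
    self-convolution of the 5-class gamete distribution.  Expanding the
    convolution recovers the usual product form, e.g.
    ``Q_4A4a = 2 P_AAAA P_aaaa + 2 P_AAAa P_Aaaa + P_AAaa^2``.
    """
    g = np.asarray(gametes, dtype=float)
    if g.shape != (5,):
        raise ValueError(f"expected 5 gamete frequencies, got shape {g.shape}")
    if np.any(g < -1e-9) or abs(g.sum() - 1.0) > 1e-6:
        raise ValueError("gamete frequencies must be a probability vector")
    return np.convolve(g, g)


def allele_equilibrium_freqs(p: float) -> np.ndarray:
    """Three-class equilibrium frequencies (Q_homA, Q_het, Q_homa) = (p^8, 1-p^8-q^8, q^8)."""
    if not 0 <= p <= 1:
        raise ValueError(f"allele frequency must lie in [0, 1], got {p!r}")
    q = 1.0 - p
    return np.array([p**8, 1.0 - p**8 - q**8, q**8])


# ordered latent gamete pairs (d1, d2) with d1 + d2 = genotype dosage
_D1, _D2 = np.divmod(np.arange(25), 5)
_PAIR_SUM = _D1 + _D2


def em_gamete_freqs(counts, tol: float = 1e-10, max_iter: int = 10_000,
                    init=None, n_starts: int = 5) -> GameteFreqEstimate:
    """EM estimate of equilibrium gamete frequencies from 9-class counts.

    The latent variable is the ordered pair of gamete dosages (d1, d2) behind
    each genotype of dosage k = d1 + d2.  The E-step allocates the count N_k
    across compatible pairs with weight ``g_d1 * g_d2 / Q_k``; the M-step sets
    each gamete frequency to its expected share of the 2N observed gametes.
    The observed-data log-likelihood is nondecreasing across iterations; the
    loop stops when the gain drops below ``tol``.

    The gamete-mixture likelihood can have multiple stationary points, so by
    default EM is restarted from a fixed deterministic set of ``n_starts``
    points — the uniform vector nudged toward the binomial distribution at the
    method-of-moments allele frequency, the binomial distribution itself, and
    seeded Dirichlet draws — and the best fit is returned.  Passing ``init``
    runs a single start from that point.
    """
    N = validate_counts(counts)
    n_tot = int(N.sum())
    if init is not None:
        starts = [np.asarray(init, dtype=float) / np.sum(init)]
    else:
        p_mom = float(np.arange(9) @ N) / (8.0 * n_tot)
        p_mom = min(max(p_mom, 1e-6), 1 - 1e-6)
        binom4 = np.array([math.comb(4, d) * p_mom**d * (1 - p_mom) ** (4 - d)
                           for d in range(5)])
        starts = [(1 - 1e-3) * np.full(5, 0.2) + 1e-3 * binom4, binom4]
        if n_starts > 2:
            extra = np.random.default_rng(12345).dirichlet(np.ones(5), n_starts - 2)
            starts.extend(np.clip(extra, 1e-6, None))
    best = None
    for g0 in starts:
        est = _em_gamete_single(N, n_tot, g0, tol, max_iter)
        if best is None or est.loglik > best.loglik:
            best = est
    return best


def _em_gamete_single(N, n_tot, g, tol, max_iter) -> GameteFreqEstimate:
    counts_pair = N[_PAIR_SUM].astype(float)
    ll_path = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Q = np.convolve(g, g)
        ll = multinomial_loglik(N, Q)
        ll_path.append(ll)
        # E-step: expected number of gametes of each dosage among the 2N drawn
        w = g[_D1] * g[_D2] / np.clip(Q[_PAIR_SUM], _EPS, None)
        resp = counts_pair * w
        expected = np.bincount(_D1, weights=resp, minlength=5) + \
            np.bincount(_D2, weights=resp, minlength=5)
        g_new = expected / (2.0 * n_tot)
        g_new = g_new / g_new.sum()
        if ll - ll_old < tol:
            converged = True
            break
        g = g_new
        ll_old = ll
    return GameteFreqEstimate(g, ll_path[-1], it, converged, np.asarray(ll_path))


def em_allele_freq(counts3, tol: float = 1e-10, max_iter: int = 10_000) -> AlleleFreqEstimate:
    """EM estimate of the A-allele frequency from dosage-unknown counts.

    ``counts3`` is (n_homA, n_het, n_homa).  The heterozygote class is a
    mixture over latent dosages d = 1..7 with weights proportional to
    ``C(8,d) p^d q^(8-d)``; the E-step resolves the mixture and the M-step is
    the usual allele-counting update
    ``p = (8 n_homA + sum_d d E[n_d]) / (8 N)``.
    """
    N = validate_counts(counts3, n_classes=3)
    n_homA, n_het, n_homa = (int(x) for x in N)
    n_tot = n_homA + n_het + n_homa

    # boundary short-circuits: a single homozygote class pins p exactly
    if n_het == 0 and n_homa == 0:
        return AlleleFreqEstimate(1.0, 0.0, 0, True, np.array([0.0]))
    if n_het == 0 and n_homA == 0:
        return AlleleFreqEstimate(0.0, 0.0, 0, True, np.array([0.0]))

    d = np.arange(1, 8)
    c8d = np.array([math.comb(8, k) for k in d], dtype=float)

    def loglik(p: float) -> float:
        Q = allele_equilibrium_freqs(p)
        return multinomial_loglik(N, Q)

    p = (8.0 * n_homA + 4.0 * n_het) / (8.0 * n_tot)
    p = min(max(p, _EPS), 1.0 - _EPS)
    ll_path = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll = loglik(p)
        ll_path.append(ll)
        q = 1.0 - p
        wd = c8d * p**d * q ** (8 - d)
        wd = wd / wd.sum()
        mean_het_dosage = float(d @ wd)
        p_new = (8.0 * n_homA + n_het * mean_het_dosage) / (8.0 * n_tot)
        p_new = min(max(p_new, _EPS), 1.0 - _EPS)
        if ll - ll_old < tol:
            converged = True
            break
        p = p_new
        ll_old = ll
    return AlleleFreqEstimate(p, ll_path[-1], it, converged, np.asarray(ll_path))


def recursive_test(counts, alpha: float = 0.0) -> TestResult:
    """Chi-square test of observed frequencies against their equilibrium proxy.

    The observed genotype frequencies seed the random-mating recursion; their
    generation-15 image is the asymptotic-equilibrium proxy P-bar, and the
    statistic is ``N * sum_j (Phat_j - Pbar_j)^2 / Pbar_j`` on 8 degrees of
    freedom.  ``alpha`` defaults to 0, the allopolyploid (no double reduction)
    case.
    """
    N = validate_counts(counts)
    n_tot = int(N.sum())
    p_hat = N / n_tot
    p_bar = equilibrium_proxy(p_hat, alpha)
    stat = 0.0
    for j in range(9):
        if p_bar[j] > 0.0:
            stat += (p_hat[j] - p_bar[j]) ** 2 / p_bar[j]
        elif p_hat[j] > 0.0:
            warnings.warn(
                "observed genotype class has zero equilibrium-proxy frequency; "
                "statistic reported as infinity",
                RuntimeWarning,
                stacklevel=2,
            )
            stat = np.inf
            break
    stat = n_tot * stat if np.isfinite(stat) else np.inf
    return TestResult("recursive", float(stat), 8, float(chi2.sf(stat, 8)), p_bar)


def gamete_lr_test(counts, tol: float = 1e-10, max_iter: int = 10_000) -> TestResult:
    """Likelihood-ratio test of the gamete-product equilibrium (4 df)."""
    N = validate_counts(counts)
    L_sat = multinomial_loglik(N, N / N.sum())
    est = em_gamete_freqs(N, tol=tol, max_iter=max_iter)
    stat = max(0.0, -2.0 * (est.loglik - L_sat))
    return TestResult("gamete", stat, 4, float(chi2.sf(stat, 4)), est)


def allele_lr_test(counts3, tol: float = 1e-10, max_iter: int = 10_000) -> TestResult:
    """Likelihood-ratio test of binomial-power equilibrium for 3-class data (1 df)."""
    N = validate_counts(counts3, n_classes=3)
    if np.count_nonzero(N) <= 1:
        # a single occupied class is always exactly fittable
        est = em_allele_freq(N, tol=tol, max_iter=max_iter)
        return TestResult("allele", 0.0, 1, 1.0, est)
    L_sat = multinomial_loglik(N, N / N.sum())
    est = em_allele_freq(N, tol=tol, max_iter=max_iter)
    stat = max(0.0, -2.0 * (est.loglik - L_sat))
    return TestResult("allele", stat, 1, float(chi2.sf(stat, 1)), est)
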