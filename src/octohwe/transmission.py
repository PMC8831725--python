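"""Transmission of octoploid genotype frequencies across random-mating generations.

Random union of the tetraploid gametes of panmictic parents gives the offspring
genotype distribution.  Two equivalent operators are provided:

* :func:`next_generation_mating` — the explicit sum over the 45 unordered
  parental mating types, each contributing the convolution of the two parents'
  gamete distributions weighted by the mating frequency;
* :func:`next_generation_pool` — the population gamete pool
  ``g = sum_i P_i * gamete_dist_i`` convolved with itself.

Under random mating these are algebraically identical; both are kept as a
cross-check and because the pool form is an O(gametes^2) fast path.

Genotype frequencies never reach an exact fixed point in finite time; they
approach a near-stationary state ("asymptotic HWE").  Generation 15 is used as
the equilibrium proxy, the horizon at which per-generation change has fallen
below practical relevance for octoploids.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .gametes import GENOTYPE_LABELS, gamete_matrix

__all__ = [
    "Trajectory",
    "validate_genotype_freqs",
    "allele_freq",
    "next_generation_pool",
    "next_generation_mating",
    "iterate",
    "equilibrium_proxy",
    "convergence_generation",
    "EQUILIBRIUM_PROXY_GENERATION",
]

#: Generation treated as the asymptotic-HWE proxy for octoploids.
EQUILIBRIUM_PROXY_GENERATION = 15


def validate_genotype_freqs(freqs, tol: float = 1e-6) -> np.ndarray:
    """Validate and return a 9-class genotype-frequency vector (ascending dosage)."""
    P = np.asarray(freqs, dtype=float)
    if P.shape != (9,):
        raise ValueError(f"expected 9 genotype frequencies, got shape {P.shape}")
    if np.any(P < -tol):
        raise ValueError("genotype frequencies must be nonnegative")
    if abs(P.sum() - 1.0) > tol:
        raise ValueError(f"genotype frequencies must sum to 1 (got {P.sum():.8f})")
    return np.clip(P, 0.0, None)


def allele_freq(freqs) -> float:
    """Frequency of allele A implied by genotype frequencies: p = sum_i i*P_i / 8."""
    P = validate_genotype_freqs(freqs)
    return float(np.arange(9) @ P / 8.0)


def next_generation_pool(parent, alpha) -> np.ndarray:
    """Offspring genotype frequencies via the population gamete pool."""
    P = validate_genotype_freqs(parent)
    g = P @ gamete_matrix(alpha)
    out = np.convolve(g, g)
    return out / out.sum()  # keep float drift from compounding across generations


@lru_cache(maxsize=64)
def _offspring_kernels(alpha: float) -> np.ndarray:
    """(9, 9, 9) array: kernels[i, j] = offspring distribution of mating i x j."""
    rows = gamete_matrix(alpha)
    K = np.empty((9, 9, 9))
    for i in range(9):
        for j in range(i, 9):
            K[i, j] = K[j, i] = np.convolve(rows[i], rows[j])
    return K


def next_generation_mating(parent, alpha) -> np.ndarray:
    """Offspring genotype frequencies as the explicit 45-mating-type sum.

    Mating type (i, j) with i <= j occurs with frequency ``P_i * P_j``
    (doubled off the diagonal) and contributes the convolution of the two
    parents' tetraploid gamete distributions.
    """
    P = validate_genotype_freqs(parent)
    K = _offspring_kernels(float(alpha))
    out = np.zeros(9)
    for i in range(9):
        if P[i] == 0.0:
            continue
        for j in range(i, 9):
            w = P[i] * P[j] * (1.0 if i == j else 2.0)
            if w:
                out += w * K[i, j]
    return out / out.sum()  # keep float drift from compounding across generations


@dataclass(frozen=True)
class Trajectory:
    """Genotype-frequency trajectory over generations 0..T at a fixed alpha."""

    freqs: np.ndarray  # (T+1, 9), ascending dosage
    alpha: float

    @property
    def generations(self) -> int:
        return self.freqs.shape[0] - 1

    def homozygote_totals(self) -> np.ndarray:
        return self.freqs[:, 0] + self.freqs[:, 8]

    def heterozygote_totals(self) -> np.ndarray:
        return self.freqs[:, 1:8].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy (generation, genotype, frequency) table for export/plotting."""
        T1, _ = self.freqs.shape
        return pd.DataFrame(
            {
                "generation": np.repeat(np.arange(T1), 9),
                "genotype": np.tile(GENOTYPE_LABELS, T1),
                "frequency": self.freqs.ravel(),
            }
        )


def iterate(start, alpha, generations: int) -> Trajectory:
    """Apply the random-mating operator ``generations`` times from ``start``."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    P = validate_genotype_freqs(start)
    out = np.empty((generations + 1, 9))
    out[0] = P
    for t in range(1, generations + 1):
        out[t] = next_generation_mating(out[t - 1], alpha)
    return Trajectory(out, float(alpha))


def equilibrium_proxy(start, alpha, generations: int = EQUILIBRIUM_PROXY_GENERATION) -> np.ndarray:
    """Genotype frequencies after ``generations`` rounds of random mating.

    The default horizon of 15 generations is the asymptotic-HWE proxy for
    octoploids.
    """
    return iterate(start, alpha, generations).freqs[-1]


def convergence_generation(start, alpha, tol: float = 1e-3, max_generations: int = 500):
    """First generation t >= 1 with L-infinity change below ``tol``.

    Returns ``None`` if the threshold is not crossed within ``max_generations``
    (a sentinel rather than an exception, so scans over parameters stay total).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    P = validate_genotype_freqs(start)
    for t in range(1, max_generations + 1):
        Q = next_generation_mating(P, alpha)
        if np.max(np.abs(Q - P)) < tol:
            return t
        P = Q
    return None
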