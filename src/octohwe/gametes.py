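"""Gamete distributions produced by octoploid genotypes under double reduction.

An octoploid genotype at a biallelic SNP is identified by its A-allele dosage
``i`` (0..8).  During polysomic meiosis it produces tetraploid gametes, modelled
here as two independent *diploid sub-gametes*: with probability ``alpha`` (the
double-reduction rate) a sub-gamete consists of the two sister chromatids of a
single uniformly chosen chromosome; with probability ``1 - alpha`` it is a
uniformly chosen unordered pair of the 28 distinct chromosome pairs.  The
tetraploid gamete distribution is the convolution of the diploid sub-gamete
distribution with itself.

All probability vectors in this package are indexed by *ascending* A-dosage
(index d = number of A alleles), so a diploid distribution is
``[P(aa), P(Aa), P(AA)]`` and a tetraploid one is
``[P(aaaa), ..., P(AAAA)]``.  :func:`gamete_table` re-orders rows and columns
by descending dosage for the conventional tabular presentation.

Arithmetic is generic: passing ``alpha`` as a :class:`fractions.Fraction`
yields exact rational output (object-dtype arrays); floats yield float arrays.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "ExtremeDoubleReductionWarning",
    "genotype_label",
    "GENOTYPE_LABELS",
    "GAMETE_LABELS",
    "diploid_gamete_dist",
    "tetraploid_gamete_dist",
    "gamete_matrix",
    "gamete_table",
]

#: Soft upper bound above which the mechanistic reading of alpha is strained.
#: Kept as an exact rational so float and Fraction inputs compare consistently.
ALPHA_SOFT_MAX = Fraction(3, 10)


class ExtremeDoubleReductionWarning(UserWarning):
    """Double-reduction rate above the biologically plausible range."""


def genotype_label(dosage: int) -> str:
    """Conventional label for an octoploid genotype, e.g. ``'8A'``, ``'5A3a'``."""
    if dosage == 8:
        return "8A"
    if dosage == 0:
        return "8a"
    return f"{dosage}A{8 - dosage}a"


#: Genotype labels in ascending dosage order (8a .. 8A).
GENOTYPE_LABELS = tuple(genotype_label(d) for d in range(9))

#: Tetraploid gamete labels in ascending dosage order.
GAMETE_LABELS = ("aaaa", "Aaaa", "AAaa", "AAAa", "AAAA")


def _check_dosage(dosage: int) -> int:
    if dosage != int(dosage) or not 0 <= dosage <= 8:
        raise ValueError(f"octoploid dosage must be an integer in 0..8, got {dosage!r}")
    return int(dosage)


def _check_alpha(alpha) -> None:
    if not 0 <= alpha <= 1:
        raise ValueError(f"double-reduction rate must lie in [0, 1], got {alpha!r}")
    if alpha > ALPHA_SOFT_MAX:
        warnings.warn(
            f"double-reduction rate {float(alpha):.3g} exceeds {float(ALPHA_SOFT_MAX)}; "
            "values this large are biologically extreme for polysomic meiosis",
            ExtremeDoubleReductionWarning,
            stacklevel=3,
        )


def _as_array(values, alpha) -> np.ndarray:
    if isinstance(alpha, Fraction):
        return np.array(values, dtype=object)
    return np.asarray(values, dtype=float)


def diploid_gamete_dist(dosage: int, alpha) -> np.ndarray:
    """Distribution of the diploid sub-gamete produced by genotype ``dosage``.

    With probability ``alpha`` the sub-gamete is a sister-chromatid pair of one
    of the 8 chromosomes; otherwise an unordered pair of distinct chromosomes
    (28 equally likely).  Returns ``[P(aa), P(Aa), P(AA)]``.
    """
    i = _check_dosage(dosage)
    _check_alpha(alpha)
    p_aa = alpha * (8 - i) / 8 + (1 - alpha) * math.comb(8 - i, 2) / 28
    p_Aa = (1 - alpha) * i * (8 - i) / 28
    p_AA = alpha * i / 8 + (1 - alpha) * math.comb(i, 2) / 28
    return _as_array([p_aa, p_Aa, p_AA], alpha)


def tetraploid_gamete_dist(dosage: int, alpha) -> np.ndarray:
    """Distribution of the tetraploid gamete produced by genotype ``dosage``.

    The tetraploid gamete is the union of two independent diploid sub-gametes,
    so its dosage distribution is the self-convolution of
    :func:`diploid_gamete_dist`.  Returns a 5-vector over gamete dosage 0..4.
    """
    d = diploid_gamete_dist(dosage, alpha)
    return np.convolve(d, d)


def gamete_matrix(alpha) -> np.ndarray:
    """9x5 matrix of gamete distributions; row d = genotype dosage d (ascending)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtremeDoubleReductionWarning)
        rows = [tetraploid_gamete_dist(i, alpha) for i in range(9)]
    _check_alpha(alpha)  # warn (at most) once for the whole table
    return np.stack(rows)


def gamete_table(alpha) -> pd.DataFrame:
    """Gamete-frequency table in the conventional descending-dosage layout.

    Rows are genotypes 8A down to 8a, columns gametes AAAA down to aaaa.
    """
    m = gamete_matrix(alpha)
    return pd.DataFrame(
        m[::-1, ::-1],
        index=pd.Index(GENOTYPE_LABELS[::-1], name="genotype"),
        columns=GAMETE_LABELS[::-1],
    )
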