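"""Synthetic genotype data and the power / type-I-error study.

The study design: build equilibrium genotype frequencies from base gamete
frequencies (dosage-known markers) or a base allele frequency (dosage-unknown
markers), perturb them off the equilibrium manifold by a stated *degree of
deviation*, draw multinomial samples of size n, run the matching
likelihood-ratio test at a nominal level, and record the rejection fraction
over replicates.  At deviation 0 the rejection fraction estimates the type-I
error; at positive deviation it estimates power.

Deviation schemes
-----------------
``absorb`` (default)
    Every heterozygote class frequency is scaled by ``1 - d`` and the freed
    probability mass is absorbed by the two homozygote classes in proportion
    to their equilibrium frequencies.  Each heterozygote frequency thus
    deviates by exactly the stated fraction, in the excess-homozygosity
    direction characteristic of populations still approaching equilibrium.
``renormalize``
    Homozygote classes scaled by ``1 + d``, heterozygote classes by ``1 - d``,
    then the whole vector renormalized.  When homozygotes are rare this
    perturbation is largely absorbed by the renormalization and the resulting
    displacement from the equilibrium manifold is much smaller.

The scheme in force is recorded in the study output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gametes import genotype_label
from .hwe import (
    allele_equilibrium_freqs,
    allele_lr_test,
    collapse_dosage,
    equilibrium_genotype_freqs,
    gamete_lr_test,
    recursive_test,
)

__all__ = [
    "DEFAULT_BASE_GAMETES",
    "SimulationConfig",
    "PowerTable",
    "deviated_freqs",
    "sample_genotype_counts",
    "run_power_study",
    "synthetic_snp_panel",
]

#: Default base gamete frequencies for the simulation study (ascending dosage).
DEFAULT_BASE_GAMETES = (0.1, 0.2, 0.4, 0.2, 0.1)


def deviated_freqs(equilibrium, deviation: float, scheme: str = "absorb") -> np.ndarray:
    """Perturb equilibrium genotype frequencies by a given degree of deviation.

    Works on any genotype-frequency vector whose first and last entries are
    the homozygote classes (9-class dosage-known or 3-class dosage-unknown).
    ``deviation=0`` returns the input unchanged.
    """
    P = np.asarray(equilibrium, dtype=float)
    if P.ndim != 1 or P.size < 3:
        raise ValueError("expected a 1-D genotype-frequency vector of length >= 3")
    if not 0 <= deviation < 1:
        raise ValueError(f"deviation must lie in [0, 1), got {deviation!r}")
    if abs(P.sum() - 1.0) > 1e-6 or np.any(P < -1e-12):
        raise ValueError("equilibrium frequencies must be a probability vector")
    if deviation == 0:
        return P.copy()
    hom_idx = np.array([0, P.size - 1])
    out = P.copy()
    if scheme == "absorb":
        het_mass = P[1:-1].sum()
        hom_mass = P[hom_idx].sum()
        out[1:-1] *= 1.0 - deviation
        freed = deviation * het_mass
        if hom_mass > 0:
            out[hom_idx] += freed * P[hom_idx] / hom_mass
        else:
            out[hom_idx] += freed / 2.0
    elif scheme == "renormalize":
        out[hom_idx] *= 1.0 + deviation
        out[1:-1] *= 1.0 - deviation
        out /= out.sum()
    else:
        raise ValueError(f"unknown deviation scheme {scheme!r}")
    return out


def sample_genotype_counts(freqs, n: int, rng) -> np.ndarray:
    """Multinomial genotype counts of sample size ``n`` from given frequencies.

    ``rng`` may be a :class:`numpy.random.Generator` or anything accepted by
    :func:`numpy.random.default_rng` (e.g. an integer seed).
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    P = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(rng)
    return rng.multinomial(n, P / P.sum())


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the power / type-I study grid."""

    sample_sizes: Sequence[int] = (50, 100, 200, 400)
    deviations: Sequence[float] = (0.0, 0.2)
    replicates: int = 1000
    level: float = 0.05
    seed: int = 0
    method: str = "gamete"  # 'gamete' (dosage-known) | 'allele' (dosage-unknown)
    base_gametes: Sequence[float] = DEFAULT_BASE_GAMETES
    base_p: float | None = None  # used by the allele method; default 0.5
    scheme: str = "absorb"

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must lie in (0, 1)")
        if self.method not in ("gamete", "allele"):
            raise ValueError(f"unknown method {self.method!r}")

    def equilibrium(self) -> np.ndarray:
        if self.method == "gamete":
            return equilibrium_genotype_freqs(np.asarray(self.base_gametes, float))
        p = 0.5 if self.base_p is None else self.base_p
        return allele_equilibrium_freqs(p)


@dataclass(frozen=True)
class PowerTable:
    """Rejection-rate grid (deviation degrees x sample sizes) with MC errors."""

    rejection: pd.DataFrame  # index: deviation, columns: sample size
    mc_se: pd.DataFrame
    config: SimulationConfig = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: deviation, n, rejection_rate, mc_se."""
        rows = []
        for dev in self.rejection.index:
            for n in self.rejection.columns:
                rows.append(
                    {
                        "deviation": dev,
                        "n": n,
                        "rejection_rate": self.rejection.loc[dev, n],
                        "mc_se": self.mc_se.loc[dev, n],
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            c = self.config
            fh.write(f"# method={c.method} level={c.level} replicates={c.replicates} "
                     f"scheme={c.scheme} seed={c.seed}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def _run_test(counts, method: str, alpha: float = 0.0):
    if method == "gamete":
        return gamete_lr_test(counts)
    if method == "allele":
        return allele_lr_test(counts)
    if method == "recursive":
        return recursive_test(counts, alpha)
    raise ValueError(f"unknown method {method!r}")


def power_cell(freqs, n: int, method: str, replicates: int, level: float,
               seed_seq: np.random.SeedSequence) -> tuple[float, float]:
    """Rejection fraction and its Monte-Carlo SE for one (frequency, n) cell."""
    rng = np.random.default_rng(seed_seq)
    rejections = 0
    for _ in range(replicates):
        counts = rng.multinomial(n, freqs)
        res = _run_test(counts, method)
        rejections += res.pvalue < level
    rate = rejections / replicates
    return rate, float(np.sqrt(rate * (1.0 - rate) / replicates))


def run_power_study(config: SimulationConfig) -> PowerTable:
    """Run the full rejection-rate grid of the study.

    A master seed spawns an independent child seed per (deviation, n) cell, so
    cells are independent and individually reproducible.
    """
    eq = config.equilibrium()
    master = np.random.SeedSequence(config.seed)
    children = iter(master.spawn(len(config.deviations) * len(config.sample_sizes)))
    rej = pd.DataFrame(index=list(config.deviations), columns=list(config.sample_sizes),
                       dtype=float)
    se = rej.copy()
    for dev in config.deviations:
        freqs = deviated_freqs(eq, dev, scheme=config.scheme)
        for n in config.sample_sizes:
            r, s = power_cell(freqs, n, config.method, config.replicates,
                              config.level, next(children))
            rej.loc[dev, n] = r
            se.loc[dev, n] = s
    rej.index.name = se.index.name = "deviation"
    return PowerTable(rej, se, config)


def synthetic_snp_panel(
    m_snps: int,
    fraction_off_equilibrium: float = 0.0,
    dosage_mode: str = "dosage",
    seed: int = 0,
    n: int = 400,
    deviation: float = 0.2,
    base_gametes: Sequence[float] = DEFAULT_BASE_GAMETES,
    scheme: str = "absorb",
    n_chromosomes: int = 9,
) -> pd.DataFrame:
    """Multi-SNP count panel with known equilibrium/deviating truth labels.

    Each SNP draws ``n`` genotypes from either the equilibrium frequencies or
    their deviated counterpart; the first ``round(m * fraction)`` SNPs are the
    deviating ones.  ``dosage_mode='dosage'`` emits nine count columns
    ``n0..n8`` (ascending A-dosage); ``'collapsed'`` emits three columns
    ``n_homA, n_het, n_homa``.  Chromosome/position metadata is synthetic,
    laid out for Manhattan-style downstream plotting.
    """
    if m_snps < 1:
        raise ValueError("m_snps must be >= 1")
    if not 0 <= fraction_off_equilibrium <= 1:
        raise ValueError("fraction_off_equilibrium must lie in [0, 1]")
    if dosage_mode not in ("dosage", "collapsed"):
        raise ValueError(f"unknown dosage_mode {dosage_mode!r}")
    eq = equilibrium_genotype_freqs(np.asarray(base_gametes, float))
    dev = deviated_freqs(eq, deviation, scheme=scheme)
    n_off = round(m_snps * fraction_off_equilibrium)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for i in range(m_snps):
        off = i < n_off
        counts = rng.multinomial(n, dev if off else eq)
        rec = {
            "snp_id": f"snp{i + 1:05d}",
            "chrom": f"chr{i % n_chromosomes + 1}",
            "pos": 1000 * (i // n_chromosomes + 1),
            "off_equilibrium": off,
        }
        if dosage_mode == "dosage":
            rec.update({f"n{d}": counts[d] for d in range(9)})
        else:
            c3 = collapse_dosage(counts)
            rec.update({"n_homA": c3[0], "n_het": c3[1], "n_homa": c3[2]})
        rows.append(rec)
    panel = pd.DataFrame(rows)
    panel.attrs.update(
        {"n": n, "deviation": deviation, "scheme": scheme, "seed": seed,
         "genotype_labels": [genotype_label(d) for d in range(9)]}
    )
    return panel
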