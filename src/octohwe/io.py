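"""File formats and batch per-SNP aHWE testing.

Count tables are TSV with a header.  Dosage-known files carry nine columns
``n0..n8`` (counts by ascending A-dosage); dosage-unknown files carry
``n_homA, n_het, n_homa``.  Optional columns ``snp_id``, ``chrom``, ``pos``
(1-based) annotate each SNP.  VCF input is collapsed to the dosage-unknown
classes: a sample call with only REF alleles is homozygote-A, only ALT is
homozygote-a, and any call containing both alleles is the mixed heterozygote
regardless of the written ploidy (true dosage is treated as unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .hwe import collapse_dosage, validate_counts
from .simulate import _run_test

__all__ = [
    "SNPRecord",
    "BatchResult",
    "read_count_table",
    "read_vcf_collapsed",
    "run_batch",
    "write_results",
    "read_results",
]

logger = logging.getLogger("octohwe")

_DOSAGE_COLS = [f"n{d}" for d in range(9)]
_COLLAPSED_COLS = ["n_homA", "n_het", "n_homa"]


@dataclass(frozen=True)
class SNPRecord:
    """Per-SNP genotype counts with optional genomic coordinates."""

    snp_id: str
    counts: np.ndarray  # length 9 (ascending dosage) or 3 (homA, het, homa)
    chrom: str = "."
    pos: int = 1

    @property
    def dosage_known(self) -> bool:
        return self.counts.size == 9


@dataclass(frozen=True)
class BatchResult:
    """Per-SNP test results plus run metadata."""

    table: pd.DataFrame  # snp_id, chrom, pos, statistic, df, pvalue, p_adjusted, deviates
    metadata: dict = field(repr=False)

    @property
    def fraction_deviating(self) -> float:
        return float(self.table["deviates"].mean())


def read_count_table(path) -> list[SNPRecord]:
    """Read a TSV count table; mode is inferred from its columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    has_dosage = all(c in df.columns for c in _DOSAGE_COLS)
    has_collapsed = all(c in df.columns for c in _COLLAPSED_COLS)
    if has_dosage and has_collapsed:
        raise ValueError(f"{path}: both dosage-known (n0..n8) and dosage-unknown "
                         "(n_homA,n_het,n_homa) columns present; use one mode per file")
    if not has_dosage and not has_collapsed:
        raise ValueError(f"{path}: expected columns n0..n8 or n_homA,n_het,n_homa")
    cols = _DOSAGE_COLS if has_dosage else _COLLAPSED_COLS
    records = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based + header
        try:
            counts = validate_counts(row[cols].to_numpy(), n_classes=len(cols))
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from exc
        pos = int(row["pos"]) if "pos" in df.columns else 1
        if pos < 1:
            raise ValueError(f"{path}: row {row_no}: pos must be >= 1")
        records.append(
            SNPRecord(
                snp_id=str(row["snp_id"]) if "snp_id" in df.columns else f"snp{row_no - 1}",
                counts=counts,
                chrom=str(row["chrom"]) if "chrom" in df.columns else ".",
                pos=pos,
            )
        )
    return records


def read_vcf_collapsed(path) -> list[SNPRecord]:
    """Read a VCF and collapse each biallelic SNP to dosage-unknown counts.

    Multi-allelic records are skipped (counted in the log); missing calls are
    excluded from the per-SNP total.
    """
    records = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_skipped += 1
                continue
            n_homA = n_het = n_homa = 0
            for sample in rec.samples.values():
                alleles = sample.get("GT")
                if alleles is None or any(a is None for a in alleles) or len(alleles) == 0:
                    continue
                allele_set = set(alleles)
                if allele_set == {0}:
                    n_homA += 1
                elif allele_set == {1}:
                    n_homa += 1
                else:
                    n_het += 1
            total = n_homA + n_het + n_homa
            if total == 0:
                n_skipped += 1
                continue
            records.append(
                SNPRecord(
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    counts=np.array([n_homA, n_het, n_homa], dtype=np.int64),
                    chrom=rec.chrom,
                    pos=rec.pos,
                )
            )
    if n_skipped:
        logger.info("read_vcf_collapsed: skipped %d non-biallelic or empty records", n_skipped)
    return records


def run_batch(records, method: str = "allele", alpha: float = 0.0,
              level: float = 0.05, correction: str = "bonferroni") -> BatchResult:
    """Test every SNP and apply multiple-testing correction.

    ``recursive`` and ``gamete`` methods require dosage-known counts; the
    ``allele`` method accepts either mode, collapsing dosage-known counts.
    Bonferroni adjustment over the number of tested SNPs is the only
    correction offered; a SNP deviates when its adjusted p-value is below
    ``level``.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    if method not in ("recursive", "gamete", "allele"):
        raise ValueError(f"unknown method {method!r}")
    records = list(records)
    if not records:
        raise ValueError("no SNP records to test")
    for rec in records:
        if method in ("recursive", "gamete") and not rec.dosage_known:
            raise ValueError(
                f"method {method!r} requires dosage-known counts, but SNP "
                f"{rec.snp_id} is dosage-unknown"
            )
    m = len(records)
    rows = []
    for rec in records:
        counts = rec.counts
        if method == "allele" and rec.dosage_known:
            counts = collapse_dosage(counts)
        res = _run_test(counts, method, alpha)
        p_adj = min(1.0, res.pvalue * m)
        rows.append(
            {
                "snp_id": rec.snp_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "n": int(rec.counts.sum()),
                "statistic": res.statistic,
                "df": res.df,
                "pvalue": res.pvalue,
                "p_adjusted": p_adj,
                "deviates": p_adj < level,
            }
        )
    table = pd.DataFrame(rows)
    metadata = {
        "method": method,
        "alpha": alpha,
        "level": level,
        "correction": correction,
        "m_tests": m,
    }
    logger.info("run_batch: %d/%d SNPs deviate from aHWE (%.1f%%) after %s at level %g",
                int(table["deviates"].sum()), m,
                100.0 * table["deviates"].mean(), correction, level)
    return BatchResult(table, metadata)


def write_results(batch: BatchResult, path) -> None:
    """Write batch results as TSV with '#'-prefixed metadata header lines.

    Adds a Manhattan-ready ``neg_log10_p`` column; an exactly-zero p-value is
    clipped to the smallest positive float and flagged in ``p_clipped``.
    """
    table = batch.table.copy()
    tiny = np.nextafter(0.0, 1.0)
    table["p_clipped"] = table["pvalue"] == 0.0
    table["neg_log10_p"] = -np.log10(np.clip(table["pvalue"].to_numpy(), tiny, None))
    with open(path, "w") as fh:
        for key, value in batch.metadata.items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results(path) -> BatchResult:
    """Round-trip reader for :func:`write_results` output."""
    metadata = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            metadata[key.strip()] = value
    table = pd.read_csv(path, sep="\t", comment="#")
    return BatchResult(table, metadata)
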