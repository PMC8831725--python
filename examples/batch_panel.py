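"""Genome-wide batch testing of a synthetic SNP panel.

Generates a labelled multi-SNP panel (half the SNPs off equilibrium), runs the
per-SNP gamete-based test with Bonferroni correction, and compares calls with
the generating truth — the same pipeline one would run on a real per-SNP count
table or a VCF collapsed to dosage-unknown classes.
"""

from octohwe import run_batch, synthetic_snp_panel, write_results
from octohwe.io import SNPRecord

panel = synthetic_snp_panel(60, fraction_off_equilibrium=0.5, seed=7, n=400,
                            deviation=0.2)
count_cols = [f"n{d}" for d in range(9)]
records = [
    SNPRecord(row["snp_id"], row[count_cols].to_numpy(), row["chrom"], row["pos"])
    for _, row in panel.iterrows()
]

batch = run_batch(records, method="gamete", level=0.05, correction="bonferroni")
truth = panel["off_equilibrium"].to_numpy()
calls = batch.table["deviates"].to_numpy()

print(f"SNPs tested:            {len(records)}")
print(f"deviating calls:        {calls.sum()} "
      f"({100 * batch.fraction_deviating:.1f}%)")
print(f"truly off equilibrium:  {truth.sum()}")
print(f"calls agreeing with truth: {(calls == truth).mean():.2%}")

write_results(batch, "scratch_batch_results.tsv")
print("\nPer-SNP results (chrom, pos, p, Bonferroni-adjusted p, -log10 p) "
      "written to scratch_batch_results.tsv,\nready for Manhattan-style plotting.")
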