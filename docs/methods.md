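# Methods

## The model

At a biallelic SNP an octoploid carries eight allele copies, so genotypes fall
into nine classes by A-dosage `i = 0..8`.  During polysomic meiosis each
genotype produces a *tetraploid* gamete (dosage 0..4).  The generative
assumption — the single assumption from which every downstream quantity is
derived — is that a tetraploid gamete is the union of two independent diploid
sub-gametes, each formed in one of two ways:

* with probability `α` (the **double-reduction rate**), the two sister
  chromatids of one uniformly chosen chromosome end up together (dosage `0`
  or `2`);
* with probability `1 − α`, an unordered pair of distinct chromosomes is
  drawn uniformly from the 28 possibilities.

For genotype dosage `i` this yields the diploid sub-gamete distribution

    P(AA) = α·i/8 + (1−α)·C(i,2)/28
    P(Aa) = (1−α)·i(8−i)/28
    P(aa) = α·(8−i)/8 + (1−α)·C(8−i,2)/28

and the tetraploid distribution is its self-convolution.  The full 9×5 gamete
table is *recomputed* from this model rather than transcribed from any printed
table, which insulates the package from typesetting ambiguities; the test
suite verifies every entry against an exhaustive enumeration of meiotic
outcomes in exact rational arithmetic, for all genotypes on the α grid
0–0.3, and checks the α = 0 constants against the conventional fractions.
Double reduction redistributes gamete classes toward the homozygous extremes
but never changes the expected gamete dosage (`i/2`), so allele frequency is
conserved.

`α` is accepted anywhere in `[0, 1]`; values above 0.3 trigger a warning (not
an error) because the mechanistic interpretation is strained there.  `α = 0`
is the allooctoploid case (no double reduction, no preferential pairing).

## Random-mating recursion and asymptotic HWE

With genotype frequencies `P_i(t)` in generation `t`, random mating over the
45 unordered parental pairs gives

    P_j(t+1) = Σ_{i1≤i2} P_i1 P_i2 · (2 − δ_{i1 i2}) · [g_i1 * g_i2]_j

where `g_i` is genotype `i`'s gamete distribution and `*` is convolution.
Because mating is random this equals the self-convolution of the population
gamete pool `ḡ = Σ_i P_i g_i`; both operators are implemented and
cross-checked to 1e-12 (the 45-term expansion is generated programmatically,
never hard-coded).  Operator outputs are renormalized to unit sum each step so
float rounding cannot compound geometrically over long trajectories.

The recursion is deterministic and infinite-population: no drift, selection,
mutation, migration, or overlapping generations.  Genotype frequencies
approach a stationary manifold but the per-generation change never reaches
exactly zero in finite time — equilibrium is *asymptotic* (aHWE).  The
practical convergence detector reports the first generation at which the
L-infinity per-generation change falls below a tolerance, default `1e-3`
(a documented package choice; the claim that octoploids are near-stationary
by generation 15 is reproduced under it, and the detector is exposed with the
tolerance as a parameter).  A 500-generation cap returns `None` rather than
raising, keeping parameter scans total.  Generation 15 is used throughout as
the equilibrium-proxy horizon (`equilibrium_proxy`).

Higher α shifts the equilibrium toward homozygotes and away from
heterozygotes, monotonically over the 0–0.3 grid, without affecting how fast
equilibrium is approached.

## The three tests

Let `N_j` (total `N`) be per-SNP genotype counts.  All log-likelihoods drop
the shared multinomial constant and use `0·log 0 = 0`; probabilities are
floored at 1e-12 inside logarithms during iteration, with exact boundary
values returned when a count configuration forces them.

**Recursive test (8 df).**  The observed frequency vector `P̂ = N/N` seeds the
recursion; its generation-15 image `P̄` is the equilibrium proxy, and the
statistic is Pearson's `N·Σ_j (P̂_j − P̄_j)²/P̄_j`, referred to χ²(8).  The
observed-start seeding mirrors the tetraploid precedent; `α` is a user
parameter defaulting to 0.  A zero proxy class with a positive observed count
reports an infinite statistic with a warning (only monomorphic degenerate
inputs can produce proxy zeros, and there the statistic is 0).

**Gamete-based test (4 df).**  Under equilibrium the nine genotype frequencies
are the self-convolution of five free gamete frequencies (4 free parameters vs
8 in the saturated multinomial).  The null MLE comes from EM on the latent
ordered gamete pair: the E-step splits `N_k` across pairs `(d1, d2)` with
`d1 + d2 = k` proportional to `g_d1 g_d2`, the M-step sets each `g_d` to its
expected share of the `2N` gametes.  The statistic is `−2(L_g − L_sat)`,
clipped at 0, referred to χ²(4).  This test is α-free.

**Allele-based test (1 df).**  Dosage-unknown genotyping resolves only three
classes (homozygote-A, mixed heterozygote, homozygote-a).  Assuming alleles
unite at random within gametes, the equilibrium class probabilities are
`(p⁸, 1 − p⁸ − q⁸, q⁸)`.  The heterozygote class is a binomial mixture over
latent dosages 1..7, resolved by EM with the allele-counting M-step
`p ← (8·n_homA + Σ_d d·E[n_d]) / (8N)`.  The statistic is `−2(L_e − L_sat)`
against the saturated trinomial, referred to χ²(1).

Degrees of freedom (8/4/1) follow the standard presentation for these tests
even though one could argue for fewer in the recursive case; this is a
deliberate fidelity choice.

**EM numerics.**  Stopping rule: log-likelihood gain below `1e-10` or 10,000
iterations (non-convergence returns the best iterate flagged
`converged=False`).  The gamete-mixture likelihood can be multimodal, so the
gamete EM runs by default from a fixed deterministic set of five start points
(uniform nudged toward the moment-binomial, the moment-binomial itself, and
three Dirichlet draws from a hard-coded seed) and keeps the best fit; the test
suite verifies that the resulting log-likelihood dominates a 0.02-resolution
simplex grid search on hundreds of random count vectors, that the allele EM
matches a bounded 1-D optimizer to 1e-6, and that per-iteration log-likelihood
paths are monotone.  LR statistics are clipped at zero and invariant under
A↔a relabeling.

## Synthetic data and the rejection-rate study

The generator draws multinomial genotype counts from equilibrium frequencies
built either from base gamete frequencies (dosage-known; default
`(0.1, 0.2, 0.4, 0.2, 0.1)`, a symmetric unimodal gamete pool at allele
frequency 0.5) or from a base allele frequency (dosage-unknown), optionally
displaced from equilibrium by a stated *degree of deviation*.

The default deviation scheme (`absorb`) scales every heterozygote class by
`1 − d` and reassigns the freed mass to the homozygote classes in proportion
to their equilibrium frequencies: each heterozygote frequency deviates by
exactly the stated fraction, in the excess-homozygosity direction
characteristic of populations still approaching equilibrium.  An alternative
(`renormalize`: homozygotes ×(1+d), heterozygotes ×(1−d), renormalize) is
provided for comparison; because the homozygote classes carry little mass at
the default base frequencies, that variant is largely undone by the
renormalization and displaces the distribution far less for the same nominal
`d`.  The scheme in force is recorded in study output metadata.

The study grid crosses deviation degrees {0, 0.2} with sample sizes
{50, 100, 200, 400}, runs 1,000 replicates per cell at level 0.05 with the
gamete-based test (the allele-based variant is a flag), and reports rejection
fractions with Monte-Carlo standard errors `sqrt(r(1−r)/replicates)` (~0.015
at mid-range rates).  A master seed spawns independent child seeds per cell,
so cells are reproducible individually and jointly.  Under the default
scheme the measured operating characteristics are: type-I error ≈ 0.01–0.04
at all n, and power ≈ 0.38 / 0.72 / 0.98 / 1.00 at n = 50/100/200/400.  The
scheme at n = 100 yields noticeably higher power than the mid-range value
sometimes quoted for comparable designs; since the deviation scheme and base
frequencies of such designs are rarely fully specified, mid-grid cells should
be compared across schemes with caution (the scheme is pluggable for exactly
this reason).

What the generator does *not* emulate: linkage between SNPs, genotyping
error, read-depth-based dosage uncertainty, finite-population drift, or
selection.  Passing tests therefore demonstrate correctness of the estimators
and operating characteristics under clean multinomial sampling, not
robustness to real-data artifacts.

## Batch testing and I/O

Count tables are TSV (nine `n0..n8` columns by ascending dosage, or three
`n_homA/n_het/n_homa` columns; one mode per file, validated with row-numbered
errors).  VCF input is collapsed to the three dosage-unknown classes: any call
containing both alleles is heterozygous regardless of written ploidy, missing
calls drop out of the per-SNP total, multi-allelic records are skipped and
logged.  Positions are 1-based.  Batch testing applies one test per SNP and
Bonferroni correction (`p_adj = min(1, p·m)`) — the only correction offered,
deliberately; a SNP is flagged as deviating when `p_adj` is below the level.
Results export as TSV with `#` metadata headers and a Manhattan-ready
`−log10 p` column (zero p-values clipped to the smallest positive float and
flagged).  No SNP QC beyond biallelic/missingness handling is applied.

## Problem sizes used in validation

The bundled validation runs use 1,000 random starting points for operator
equivalence, 200 random count vectors per EM-oracle comparison, 1,000
replicates per rejection-rate cell, and 100-SNP synthetic panels at n = 400 —
sizes at which Monte-Carlo error is small relative to the effects being
checked while the full suite stays fast.

## Known limitations

* The recursive test's chi-square reference with 8 df is a large-sample
  approximation inherited from the tetraploid formulation; small samples make
  it conservative-to-erratic in sparse classes.
* The equilibrium proxy is the generation-15 image, not the true asymptotic
  limit; the difference is below 1e-4 (L∞) for the starts examined.
* Estimation of α from data is out of scope; α enters only as a user-supplied
  parameter of the recursive test and the transmission model.
* The deviation scheme is a modelling choice; only its direction (heterozygote
  deficit) and magnitude parameterization are fixed by the design, and other
  schemes of the same nominal degree displace distributions differently.
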