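# Methods

## The missingness model

The unit of missingness throughout is the *fully-missing diploid
genotype*: both allele calls absent ("./." in VCF). Half-missing
genotypes ("./0") occur in real VCFs and are reported separately in the
summary tables, but they do not enter the per-site proportions x₁…x_N —
the profile counts only samples with no call at all. All samples are
assumed diploid; non-diploid GT fields are a hard error on input.

### Dispersal replication

Given a template profile x of length N and a target length M, the
engine produces y₁…y_M:

* **M ≤ N.** The template index range [1..N] is partitioned into exactly
  M contiguous non-empty blocks, block j covering
  ⌊(j−1)N/M⌋+1 … ⌊jN/M⌋. y_j is a uniformly random element of block j's
  values. The proportional boundary rule reduces to equal blocks of N/M
  indices whenever M divides N and guarantees exactly M non-empty blocks
  otherwise (a fixed block size of ⌈N/M⌉ would leave fewer than M blocks
  whenever N mod M ≠ 0).
* **M > N.** The target range [1..M] is partitioned into N blocks by the
  mirrored rule. Target block j < N is filled with independent draws
  from U(min(x_j, x_{j+1}), max(x_j, x_{j+1})), taken on the half-open
  interval [a, b) with U(a, a) ≡ a; the last block draws from the pair
  (x_{N−1}, x_N), i.e. the pattern at the template's end is assumed to
  extend. For N = 1 every y_j = x₁.

With M = N both branches are exactly the identity for any seed — the
single most load-bearing invariant in the test suite. Within a block the
M ≤ N case draws independently (sampling with or without replacement is
moot: each y_j comes from its own disjoint block).

The stratification loses resolution when M and N are wildly different:
with M ≪ N each y_j summarizes a huge block by a single draw, and with
M ≫ N long runs of y come from a single uniform interval. This is
inherent to the block construction, not an implementation limit.

### Beta baseline

The position-agnostic alternative fits Beta(α, β) to the profile's mean
μ and standard deviation σ by the method of moments:

    ν = μ(1−μ)/σ² − 1,   α = μν,   β = (1−μ)ν

feasible only when 0 < σ² < μ(1−μ); an infeasible σ (including σ = 0
from a constant profile) is an error rather than a silent clamp. The
template fit uses the population (divide-by-N) standard deviation; with
N in the thousands the distinction from the sample estimator is far
below any tolerance used here, but the choice is fixed so runs are
reproducible. Beta draws lie in (0, 1) by construction, so no clipping
is ever applied.

### Realizing a plan

At site j each sample independently becomes fully missing with
probability y_j (already-missing genotypes stay missing; nothing else in
the record is touched). The per-sample Bernoulli rule is the simplest
exchangeable realization; `--exact-count` instead masks round(y_j·n)
uniformly chosen samples, which makes the realized proportion
deterministic — the fixture generator uses the exact-count rule for the
same reason, so generated templates are usable as test oracles. The
engine only ever *produces* fully-missing genotypes; half-missing calls
can enter through input data but are never created.

## Degradation operators

* **unphase** swaps the left/right alleles of each genotype with
  probability ½ and clears all phase flags; allele content is untouched.
* **depolarize** swaps REF and ALT with probability ½ per biallelic
  site, flipping every allele index (0 ↔ 1, missing preserved) — a pure
  relabeling that conserves per-site nucleotide frequencies. Ancestral
  allele knowledge (the `AA` INFO tag on output) is dropped whether or
  not an individual site swapped.
* **deaminate** takes two probabilities: each biallelic site is a
  transition site with probability p_t (drawn once per site, with no
  inspection of whether REF/ALT are chemically a transition pair — the
  model is deliberately abstract), and at transition sites each
  reference-allele *copy* independently converts to the alternative
  allele with probability p_d. A heterozygote can lose one or both REF
  copies, mirroring per-molecule damage. Only REF→ALT conversion is
  modeled; the ALT count per site never decreases. Expected conversion
  fraction of REF copies is p_t·p_d.
* **pseudohaploidize** replaces each genotype with a homozygote for one
  of its own two alleles chosen uniformly — the standard low-coverage
  ancient-DNA representation. Homozygotes are fixed points, fully-missing
  genotypes are untouched, and half-missing genotypes become homozygous
  for their single observed allele (drawing the absent slot would
  silently inflate missingness). Heterozygotes land on 0/0 or 1/1 with
  probability ½ each, so the expected ALT frequency is preserved. Output
  is unphased.

Operators restricted to biallelic sites (depolarize, deaminate,
pseudohaploidize) pass multiallelic and monomorphic records through
untouched, logging the skip count. When several operators are requested
in one run the order is fixed: depolarize → deaminate →
pseudohaploidize → unphase → missingness. Damage acts on the true
genotypes before representation changes, and missingness goes last so
realized proportions are not diluted by later operators. All randomness
flows from a single seeded `numpy.random.Generator`, so (input, flags,
seed) determine every output byte.

## Formats

* **VCF** (4.x, plain or bgzipped) is read through cyvcf2; only GT is
  kept, with phase taken from the separator. Output is a minimal VCF 4.2
  (GT-only FORMAT, contigs inferred from the data) written directly, so
  the output contract is byte-stable; records lacking GT are read as
  all-missing with a warning. A matrix still carrying polarization emits
  `AA=<REF>` so depolarization is observable downstream.
* **ms dialect** (Hudson 2002): replicates delimited by `//`, a
  `segsites:` count, fractional `positions:`, then 0/1 haplotype rows.
  Consecutive haplotype pairs form diploid samples; allele 0 = ancestral
  = REF. Fractions map to integer positions by ⌊f·L⌋+1 on a user-chosen
  segment length L (default 1,000,000 bp), with ties bumped to the next
  free integer — deterministic and order-preserving; a 1e-9 epsilon
  guards exactly representable products against float round-down.
  Multi-replicate input splits into `_rep<k>` outputs, k from 1. ms
  *output* is refused whenever the matrix holds missing alleles or
  unphased genotypes, since the format cannot express either.
* **EIGENSTRAT** triplets decode per the AADR convention: each .geno
  digit is the count of REFERENCE-allele copies (2 → 0/0, 1 → 0/1,
  0 → 1/1, 9 → ./.). EIGENSTRAT carries no phase, so converted genotypes
  are unphased, and no ancestral annotation.

## Evaluation statistics

Per-site and per-sample missingness tables follow PLINK's .lmiss/.imiss
column meanings (with an extra N_HALF column for half-missing calls).
Histograms use 50 equal-width bins on [0, 1], left-closed with the last
bin right-closed so a proportion of exactly 1.0 is counted. KL
divergence is computed in natural log; since KL is undefined when
q_i = 0 < p_i, half an observation is added to every bin of both
histograms before normalizing (a Jeffreys-style pseudocount). Raw bin
counts are therefore kept in the histogram object. The pseudocount
perturbs KL by O(bins/2n); at the site counts used here (≥ 2,000) the
effect is orders of magnitude below the differences being compared, and
the dispersal-vs-beta *ordering* — the quantity the evaluation rests
on — is additionally invariant to the log base.

## Synthetic data

The fixture generator emulates the two inputs the tool sees in practice.
`make_template` produces a biallelic matrix whose per-site missingness
follows a chosen spatial shape (constant, linear ramp, sinusoid, step
blocks, or i.i.d. beta draws), realized by exact counts so the template
profile is deterministic up to 1/n-samples quantization; non-missing
genotypes are unphased draws at per-site allele frequencies uniform on
[0.05, 0.95]. `make_clean_segment` produces an idealized phased,
polarized, missing-free segment with derived-allele counts drawn from
the neutral 1/k site-frequency spectrum. The ramp-to-0.9 template used
in tests (2,000 sites × 100 samples) is a deliberately strong spatial
trend; its overall mean (0.45) and spread are in the range reported for
large ancient-DNA panels.

What these fixtures do *not* emulate: linkage disequilibrium, correlated
missingness across samples, mappability-driven missingness blocks,
genotype likelihoods, or ascertainment. Tests passing on them show the
engines reproduce the *profile* they are given, not that any particular
empirical panel is matched.

For the coalescent-scale check, the test suite and acceptance script
simulate a neutrally evolving 10 Mb segment for 200 diploid samples
(Ne = 10,000, μ = 1.29×10⁻⁸, ρ = 1×10⁻⁸ per bp per generation) with
msprime and count segregating sites; the Watterson expectation
θ_W·Σ_{i<400} 1/i ≈ 3.4×10⁴ anchors the result, and single replicates
land within a few percent of it. The full-scale simulation takes about
a second, so no scaled-down variant is needed.

## Known limitations

* Missingness is independent across samples within a site; real panels
  show strong per-sample coverage structure (the per-sample marginal is
  uniform here).
* The dispersal engine carries no notion of genomic coordinates — blocks
  are index-based, so templates and targets with very different site
  densities are aligned by rank, not position.
* Deamination is symmetric in the abstract (no C→T vs G→A strand
  distinction) and never converts ALT→REF.
* Ploidy other than 2, structural variants, and genotype dosages are out
  of scope.
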