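# genodegrade

Degrade idealized simulated genotypes into realistic ones.

Coalescent and forward simulators emit genotypes under idyllic conditions:
every call is present, phased, and polarized (the ancestral allele is
known). Empirical panels — ancient-DNA data above all — are none of those
things, and the *position* of missing genotypes along a segment is far
from random: it concentrates in regions of low complexity and poor
mappability. Methods benchmarked only on pristine simulations can
therefore behave very differently on real data.

`genodegrade` is for population geneticists who want their simulated
test data to misbehave the way real data does. It extracts both the
**distribution** and the **positional dispersal** of fully-missing
diploid genotypes from a template dataset and replicates them onto a
simulated segment of any size, alongside the standard degradation
operators (unphasing, REF/ALT depolarization, deamination-style damage,
pseudohaploidization), conversion between VCF, ms-style and EIGENSTRAT
formats, and PLINK-style missingness summaries with histogram /
KL-divergence evaluation.

## The method

Let *x₁…x_N* be the proportion of samples with both genotype calls
missing at each of the template's *N* sites, and let *M* be the number of
target sites.

* **M ≤ N** (downsampling): the template index range is partitioned into
  *M* contiguous blocks, block *j* spanning indices
  ⌊(j−1)N/M⌋+1 … ⌊jN/M⌋; the target proportion *y_j* is a uniformly
  random element of block *j*'s values. With *M = N* this is exactly the
  identity.
* **M > N** (upsampling): the target range is partitioned into *N*
  contiguous blocks by the mirror rule; block *j < N* is filled with
  i.i.d. draws from *U*(min(x_j, x_{j+1}), max(x_j, x_{j+1})) on
  [a, b), and the last block reuses the pair (x_{N−1}, x_N) — the
  pattern at the template's end is assumed to extend.

The conventional alternative — fitting a Beta(α, β) to the profile's
mean and standard deviation by the method of moments and drawing each
*y_j* i.i.d. — is also provided, both as a baseline and as a
missingness source in its own right. A plan *y* is realized by marking
each sample fully missing ("./.") at site *j* independently with
probability *y_j* (or, with `--exact-count`, by masking exactly
round(y_j·n) samples).

Agreement between missingness distributions is measured by binning
per-site proportions into 50 equal-width bins on [0, 1] and computing
the Kullback–Leibler divergence KL(p‖q) = Σ pᵢ ln(pᵢ/qᵢ) in nats, with
half an observation added to every bin of both histograms before
normalizing so empty bins stay finite.

## Worked example

Generate a template whose missingness ramps from 0 to 0.9 across 2,000
sites (a stand-in for an empirical ancient-DNA panel), a clean simulated
segment, and degrade the segment with the template's pattern:

```sh
python -c "
import genodegrade as gd
t = gd.make_template(gd.TemplateSpec(2000, 100, ('ramp', 0.0, 0.9), seed=1))
gd.write_vcf(t, 'template.vcf')
gd.write_vcf(gd.make_clean_segment(2000, 50, seed=2), 'clean.vcf')
"
genodegrade clean.vcf --out degraded --missing-template template.vcf \
    --unphase --pseudohaploid --stats --seed 42
```

which prints `degraded.vcf` and writes a log:

```
genodegrade 0.1.0
input: clean.vcf (format vcf, 1 replicate(s))
seed: 42
operator order: depolarize -> deaminate -> pseudohaploidize -> unphase -> missingness
replicate 1: 2000 sites, 50 samples -> degraded.vcf
replicate 1: mean missingness 0.4512, sd 0.2683
```

The realized mean missingness (0.4512) tracks the template ramp's mean
(0.45); `degraded.lmiss.tsv` / `degraded.imiss.tsv` hold the per-site
and per-sample tables. Comparing 50-bin histograms of per-site
missingness against the template:

```
KL(template || degraded)       = 0.0979
KL(template || beta-degraded)  = 0.1267
```

the dispersal-replicated segment is closer to the template than the
beta-model baseline — the package's headline property, which holds in
well over 80% of seeded repetitions for spatially structured templates
(see `tests/test_acceptance.py`).

Other common invocations:

```sh
# split a multi-replicate ms stream into per-replicate VCFs
genodegrade sims.ms --out rep --segment-length 1000000

# EIGENSTRAT triplet (prefix.geno/.snp/.ind) to VCF
genodegrade panel.geno --format eigenstrat --out panel

# beta-model missingness from explicit moments, plus deamination
genodegrade clean.vcf --out deg --missing-beta 0.56 0.21 \
    --deaminate 0.6 0.3 --seed 7
```

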