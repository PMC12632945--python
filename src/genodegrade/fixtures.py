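"""Synthetic genotype data with controlled missingness structure.

These generators stand in for the two kinds of data the package operates
on: an empirical *template* whose per-site missingness follows a chosen
spatial shape (constant, linear ramp, sinusoid, step blocks, or i.i.d.
beta draws), and an idealized *clean segment* — fully phased, polarized
and missing-free, with derived-allele counts drawn from the neutral
1/i site-frequency spectrum.

Template missingness is realized by exact counts (round(x_i * n) samples
masked per site) so the template's profile is a deterministic function of
the requested shape, up to 1/n_samples quantization — which makes the
generated profile usable as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class TemplateSpec:
    """Recipe for a synthetic template matrix.

    ``shape`` selects the spatial profile of missingness:

    - ``("constant", c)``: every site has proportion c
    - ``("ramp", a, b)``: linear ramp a -> b across the segment
    - ``("sinusoid", lo, hi, cycles)``: oscillation between lo and hi
    - ``("blocks", (breakpoint_fracs), (levels))``: piecewise-constant;
      len(levels) == len(breakpoint_fracs) + 1
    - ``("beta", alpha, beta)``: i.i.d. Beta(alpha, beta) per site
    """

    n_sites: int
    n_samples: int
    shape: tuple = ("constant", 0.0)
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.95)

    def profile_values(self) -> np.ndarray:
        """The intended per-site missing proportions, before quantization."""
        S = self.n_sites
        kind, *params = self.shape
        if kind == "constant":
            (c,) = params
            x = np.full(S, float(c))
        elif kind == "ramp":
            a, b = params
            x = np.linspace(a, b, S)
        elif kind == "sinusoid":
            lo, hi, cycles = params
            t = np.linspace(0, 2 * np.pi * cycles, S)
            x = lo + (hi - lo) * (1 + np.sin(t)) / 2
        elif kind == "blocks":
            breaks, levels = params
            if len(levels) != len(breaks) + 1:
                raise ValueError("blocks shape needs one more level than "
                                 "breakpoints")
            idx = np.searchsorted(np.asarray(breaks) * S,
                                  np.arange(S), side="right")
            x = np.asarray(levels, dtype=float)[idx]
        elif kind == "beta":
            a, b = params
            x = np.random.default_rng(self.seed + 1).beta(a, b, size=S)
        else:
            raise ValueError(f"unknown profile shape {kind!r}")
        if ((x < 0) | (x > 1)).any():
            raise ValueError("profile shape produces values outside [0, 1]")
        return x


def make_template(spec: TemplateSpec) -> GenotypeMatrix:
    """Generate a biallelic template whose missingness follows the spec.

    Per site, round(x_i * n_samples) samples are masked fully missing
    (chosen at random but deterministically for the seed); the remaining
    genotypes are unphased diploid draws at a per-site ALT frequency
    uniform over ``maf_range``.
    """
    if spec.n_sites < 1 or spec.n_samples < 1:
        raise ValueError("need at least one site and one sample")
    rng = np.random.default_rng(spec.seed)
    S, n = spec.n_sites, spec.n_samples
    x = spec.profile_values()
    freqs = rng.uniform(*spec.maf_range, size=S)
    alleles = (rng.random((S, n, 2)) < freqs[:, None, None]).astype(np.int16)
    for i in range(S):
        k = int(round(x[i] * n))
        if k:
            alleles[i, rng.choice(n, size=k, replace=False)] = MISSING
    phased = np.zeros((S, n), dtype=bool)
    return GenotypeMatrix(
        [f"tmpl_{j + 1}" for j in range(n)],
        ["1"] * S, np.arange(1, S + 1) * 10, ["."] * S,
        ["A"] * S, [("G",)] * S, alleles, phased, polarized=False)


def make_clean_segment(n_sites: int, n_samples: int,
                       seed: int = 0,
                       segment_length: int | None = None
                       ) -> GenotypeMatrix:
    """Generate an idealized segment: phased, polarized, no missing data.

    Per site a derived-allele count k in 1..2n-1 is drawn with probability
    proportional to 1/k (the neutral site-frequency spectrum) and assigned
    to k uniformly chosen haploid chromosomes.  Positions are distinct and
    increasing across ``segment_length`` bp (default 10 bp per site).
    """
    if n_sites < 1 or n_samples < 1:
        raise ValueError("need at least one site and one sample")
    rng = np.random.default_rng(seed)
    S, n2 = n_sites, 2 * n_samples
    if segment_length is None:
        segment_length = 10 * S
    if segment_length < S:
        raise ValueError("segment_length must allow distinct positions")
    ks = np.arange(1, n2)
    sfs = (1.0 / ks) / (1.0 / ks).sum()
    counts = rng.choice(ks, size=S, p=sfs)
    hap = np.zeros((S, n2), dtype=np.int16)
    for i in range(S):
        hap[i, rng.choice(n2, size=counts[i], replace=False)] = 1
    alleles = np.stack([hap[:, 0::2], hap[:, 1::2]], axis=2)
    phased = np.ones((S, n_samples), dtype=bool)
    pos = np.sort(rng.choice(np.arange(1, segment_length + 1), size=S,
                             replace=False))
    return GenotypeMatrix(
        [f"sim_{j + 1}" for j in range(n_samples)],
        ["1"] * S, pos, ["."] * S,
        ["A"] * S, [("T",)] * S, alleles, phased, polarized=True)
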