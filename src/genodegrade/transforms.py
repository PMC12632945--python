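"""Genotype degradation operators: unphase, depolarize, deaminate,
pseudohaploidize.

All four operators return a new matrix, never mutate their input, and draw
every random decision from the supplied ``numpy.random.Generator`` so a run
is reproducible from (input, seed).  Operators whose definition only makes
sense at biallelic sites (depolarize, deaminate, pseudohaploidize) pass
multiallelic or monomorphic records through untouched and log how many were
skipped.

When several operators are combined on one run the canonical order is
depolarize -> deaminate -> pseudohaploidize -> unphase -> missingness:
chemical damage acts on the true genotypes before representation changes,
and missingness goes last so realized proportions are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeaminationModel:
    """Two-parameter post-mortem damage model.

    ``p_transition`` is the probability a site is designated a transition
    site; ``p_deaminate`` the probability that, at a transition site, a
    reference-allele copy converts to the alternative allele (the apparent
    C->T / G->A substitution).  The model is abstract: it never inspects
    whether REF/ALT are chemically a transition pair.
    """

    p_transition: float
    p_deaminate: float

    def __post_init__(self) -> None:
        for name in ("p_transition", "p_deaminate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def unphase(matrix: GenotypeMatrix,
            rng: np.random.Generator) -> GenotypeMatrix:
    """Remove phase: swap left/right alleles with probability 1/2 each
    genotype, and clear every phase flag.  Allele content is unchanged."""
    out = matrix.copy()
    if out.n_sites and out.n_samples:
        swap = rng.random((out.n_sites, out.n_samples)) < 0.5
        a = out.alleles
        left = a[:, :, 0].copy()
        a[:, :, 0] = np.where(swap, a[:, :, 1], a[:, :, 0])
        a[:, :, 1] = np.where(swap, left, a[:, :, 1])
    out.phased[:] = False
    return out


def depolarize(matrix: GenotypeMatrix,
               rng: np.random.Generator) -> GenotypeMatrix:
    """Remove polarization: at each biallelic site, swap REF and ALT with
    probability 1/2.

    A swap exchanges the REF/ALT strings and flips every allele index
    (0 <-> 1, missing preserved), so the nucleotides each genotype carries
    are identical before and after — the swap is pure relabeling.  Any
    ancestral-allele knowledge is dropped (the matrix is no longer
    polarized) whether or not individual sites happened to swap.
    """
    out = matrix.copy()
    bi = out.biallelic_mask()
    n_skip = out.n_sites - int(bi.sum())
    if n_skip:
        logger.info("depolarize: skipped %d non-biallelic site(s)", n_skip)
    swap = bi & (rng.random(out.n_sites) < 0.5)
    for i in np.flatnonzero(swap):
        out.ref[i], out.alt[i] = out.alt[i][0], (out.ref[i],)
    sel = out.alleles[swap]
    zeros = sel == 0
    sel[sel == 1] = 0
    sel[zeros] = 1
    out.alleles[swap] = sel
    out.polarized = False
    return out


def deaminate(matrix: GenotypeMatrix, model: DeaminationModel,
              rng: np.random.Generator) -> GenotypeMatrix:
    """Introduce deamination-style damage.

    Each biallelic site is independently a transition site with probability
    ``p_transition``; there, every reference-allele copy (index 0)
    independently becomes the alternative allele (index 1) with probability
    ``p_deaminate``.  Non-reference and missing alleles are untouched, so
    the per-site ALT count can only increase.
    """
    out = matrix.copy()
    bi = out.biallelic_mask()
    n_skip = out.n_sites - int(bi.sum())
    if n_skip:
        logger.info("deaminate: skipped %d non-biallelic site(s)", n_skip)
    if not out.n_sites or not out.n_samples:
        return out
    transition = bi & (rng.random(out.n_sites) < model.p_transition)
    flip = (rng.random(out.alleles.shape) < model.p_deaminate)
    convert = transition[:, None, None] & flip & (out.alleles == 0)
    out.alleles[convert] = 1
    return out


def pseudohaploidize(matrix: GenotypeMatrix,
                     rng: np.random.Generator) -> GenotypeMatrix:
    """Collapse each genotype to a homozygote for one of its own alleles.

    Standard low-coverage ancient-DNA practice: at each biallelic site,
    each sample's reported genotype is a homozygote for one allele sampled
    uniformly from its own two calls (a heterozygote becomes 0/0 or 1/1
    with probability 1/2 each; homozygotes are fixed points).
    Fully-missing genotypes are untouched; half-missing genotypes become
    homozygous for their single observed allele.  The result is unphased.
    """
    out = matrix.copy()
    bi = out.biallelic_mask()
    n_skip = out.n_sites - int(bi.sum())
    if n_skip:
        logger.info("pseudohaploidize: skipped %d non-biallelic site(s)",
                    n_skip)
    if out.n_sites and out.n_samples:
        a = out.alleles
        pick_right = rng.random((out.n_sites, out.n_samples)) < 0.5
        chosen = np.where(pick_right, a[:, :, 1], a[:, :, 0])
        other = np.where(pick_right, a[:, :, 0], a[:, :, 1])
        # a missing slot never wins against an observed allele
        chosen = np.where(chosen == MISSING, other, chosen)
        site_sel = bi[:, None] & (chosen != MISSING)
        a[:, :, 0] = np.where(site_sel, chosen, a[:, :, 0])
        a[:, :, 1] = np.where(site_sel, chosen, a[:, :, 1])
        out.phased[bi] = False
    return out
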