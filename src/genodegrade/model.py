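"""In-memory representation of diploid genotype data.

The central container is :class:`GenotypeMatrix`, a numpy-backed sites ×
samples matrix of diploid genotypes.  Allele values are small non-negative
integers indexing ``[REF] + ALT`` at each site; a missing allele call is the
sentinel :data:`MISSING` (-1).  Per-genotype phase is tracked as a boolean.

All samples are assumed diploid throughout the package: every genotype has
exactly two allele slots (``left`` and ``right`` — the ordering is meaningful
for phased data and is what unphasing randomizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Sentinel allele value for a missing call ("." in VCF).
MISSING: int = -1


class EmptyMatrixError(ValueError):
    """Raised when an operation requires at least one site / sample."""


@dataclass(frozen=True)
class Genotype:
    """A single diploid genotype: two allele slots and a phase flag."""

    left: int
    right: int
    phased: bool = False

    @property
    def is_fully_missing(self) -> bool:
        """True iff both allele calls are missing ("./.")."""
        return self.left == MISSING and self.right == MISSING

    @property
    def is_half_missing(self) -> bool:
        """True iff exactly one of the two allele calls is missing."""
        return (self.left == MISSING) != (self.right == MISSING)


@dataclass
class Site:
    """One variant record: coordinates, alleles and per-sample genotypes.

    ``pos`` is 1-based, as in VCF.  ``alt_alleles`` may be empty (a
    monomorphic record) or hold several strings (multiallelic).
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotypes: list[Genotype]

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)


def is_biallelic(site: Site) -> bool:
    """True iff the site has exactly one alternative allele."""
    return len(site.alt_alleles) == 1


def site_missing_proportion(site: Site) -> float:
    """Proportion of samples with BOTH genotype calls missing at ``site``.

    Half-missing genotypes (exactly one "." slot) do not count: the
    missingness profile is defined over fully-missing genotypes only.
    """
    if not site.genotypes:
        raise EmptyMatrixError("site has no genotypes (empty dataset)")
    n_full = sum(1 for g in site.genotypes if g.is_fully_missing)
    return n_full / len(site.genotypes)


class GenotypeMatrix:
    """Sites × diploid-samples genotype matrix.

    Backed by three aligned numpy arrays:

    ``alleles``
        int16 array of shape ``(n_sites, n_samples, 2)``; :data:`MISSING`
        marks an absent call.
    ``phased``
        bool array of shape ``(n_sites, n_samples)``.
    ``pos``
        int64 array of 1-based positions.

    plus per-site metadata lists (``chrom``, ``ids``, ``ref``, ``alt``).
    ``polarized`` records whether the ancestral allele is still known to be
    REF (true for freshly simulated data; cleared by depolarization).
    """

    def __init__(
        self,
        sample_names: Sequence[str],
        chrom: Sequence[str],
        pos: Sequence[int],
        ids: Sequence[str],
        ref: Sequence[str],
        alt: Sequence[tuple[str, ...]],
        alleles: np.ndarray,
        phased: np.ndarray,
        polarized: bool = False,
    ):
        self.sample_names = list(sample_names)
        self.chrom = list(chrom)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ids = list(ids)
        self.ref = list(ref)
        self.alt = [tuple(a) for a in alt]
        self.alleles = np.asarray(alleles, dtype=np.int16)
        self.phased = np.asarray(phased, dtype=bool)
        self.polarized = polarized
        self._validate()

    def _validate(self) -> None:
        n_sites, n_samples = len(self.chrom), len(self.sample_names)
        if self.alleles.shape != (n_sites, n_samples, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n_sites} sites x {n_samples} samples x 2 (diploid)"
            )
        if self.phased.shape != (n_sites, n_samples):
            raise ValueError("phase array shape mismatch")
        for name, seq in (("pos", self.pos), ("ids", self.ids),
                          ("ref", self.ref), ("alt", self.alt)):
            if len(seq) != n_sites:
                raise ValueError(f"{name} length != site count")
        # allele indices must be MISSING or < 1 + n_alt at each site
        n_alt = np.fromiter((len(a) for a in self.alt), dtype=np.int16,
                            count=n_sites)
        if n_sites and n_samples:
            too_big = self.alleles > n_alt[:, None, None]
            too_small = self.alleles < MISSING
            if too_big.any() or too_small.any():
                i = int(np.argwhere(too_big | too_small)[0][0])
                raise ValueError(
                    f"allele index out of range at site {self.chrom[i]}:"
                    f"{self.pos[i]} (allele count {1 + len(self.alt[i])})"
                )

    # -- shape ---------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    # -- views ---------------------------------------------------------
    def site(self, i: int) -> Site:
        """Materialize site ``i`` as a :class:`Site` view (copy)."""
        gts = [
            Genotype(int(self.alleles[i, s, 0]), int(self.alleles[i, s, 1]),
                     bool(self.phased[i, s]))
            for s in range(self.n_samples)
        ]
        return Site(self.chrom[i], int(self.pos[i]), self.ids[i],
                    self.ref[i], self.alt[i], gts)

    def sites(self) -> Iterator[Site]:
        for i in range(self.n_sites):
            yield self.site(i)

    @classmethod
    def from_sites(cls, sample_names: Sequence[str], sites: Sequence[Site],
                   polarized: bool = False) -> "GenotypeMatrix":
        n_sites, n_samples = len(sites), len(sample_names)
        alleles = np.full((n_sites, n_samples, 2), MISSING, dtype=np.int16)
        phased = np.zeros((n_sites, n_samples), dtype=bool)
        for i, s in enumerate(sites):
            if len(s.genotypes) != n_samples:
                raise ValueError(
                    f"site {s.chrom}:{s.pos} has {len(s.genotypes)} "
                    f"genotypes for {n_samples} samples"
                )
            for j, g in enumerate(s.genotypes):
                alleles[i, j, 0] = g.left
                alleles[i, j, 1] = g.right
                phased[i, j] = g.phased
        return cls(
            sample_names,
            [s.chrom for s in sites],
            [s.pos for s in sites],
            [s.id for s in sites],
            [s.ref_allele for s in sites],
            [s.alt_alleles for s in sites],
            alleles,
            phased,
            polarized=polarized,
        )

    # -- vectorized missingness helpers --------------------------------
    def fully_missing_mask(self) -> np.ndarray:
        """(n_sites, n_samples) bool: both allele slots missing."""
        return (self.alleles == MISSING).all(axis=2)

    def half_missing_mask(self) -> np.ndarray:
        """(n_sites, n_samples) bool: exactly one allele slot missing."""
        return (self.alleles == MISSING).sum(axis=2) == 1

    def missing_proportions(self) -> np.ndarray:
        """Per-site proportion of fully-missing samples (vectorized)."""
        if self.n_sites == 0 or self.n_samples == 0:
            raise EmptyMatrixError("matrix has no sites or no samples")
        return self.fully_missing_mask().mean(axis=1)

    def biallelic_mask(self) -> np.ndarray:
        """(n_sites,) bool: exactly one ALT allele."""
        return np.fromiter((len(a) == 1 for a in self.alt), dtype=bool,
                           count=self.n_sites)

    # -- copying / equality --------------------------------------------
    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_names), list(self.chrom), self.pos.copy(),
            list(self.ids), list(self.ref), list(self.alt),
            self.alleles.copy(), self.phased.copy(), self.polarized,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_names == other.sample_names
            and self.chrom == other.chrom
            and np.array_equal(self.pos, other.pos)
            and self.ids == other.ids
            and self.ref == other.ref
            and self.alt == other.alt
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.phased, other.phased)
            and self.polarized == other.polarized
        )

    def __repr__(self) -> str:
        return (f"GenotypeMatrix({self.n_sites} sites x "
                f"{self.n_samples} samples)")
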