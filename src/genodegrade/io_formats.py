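"""Readers and writers for VCF, ms-style, and EIGENSTRAT genotype data.

VCF reading goes through cyvcf2; writing emits a minimal VCF 4.2 by hand so
the output contract (GT-only FORMAT, phase rendered as ``|`` vs ``/``,
missing alleles as ``.``, optional ``AA`` ancestral-allele tag) is exact and
stable.  The ms dialect is Hudson's: replicates delimited by ``//``, a
``segsites:`` count, fractional ``positions:`` in (0, 1), then one 0/1 row
per haploid chromosome.  EIGENSTRAT triplets (.geno/.snp/.ind) follow the
AADR convention: each .geno character is the count of REFERENCE-allele
copies (0, 1, 2) with 9 meaning missing.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from cyvcf2 import VCF

from .model import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

#: Default segment length (bp) for mapping fractional ms positions.
DEFAULT_SEGMENT_LENGTH = 1_000_000


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF into a :class:`GenotypeMatrix`.

    Only the GT field is kept.  Phase is taken from the separator (``|``
    phased, ``/`` unphased); ``./.`` and ``.|.`` become fully-missing
    genotypes.  Records lacking a GT field are treated as all-missing with
    a warning.  Non-diploid genotypes are an error: the whole package
    assumes diploid samples.

    The matrix is flagged ``polarized`` iff every record carries an ``AA``
    INFO tag equal to its REF allele.
    """
    vcf = VCF(str(path), gts012=False)
    sample_names = list(vcf.samples)
    chrom, pos, ids, ref, alt = [], [], [], [], []
    allele_rows, phase_rows = [], []
    polarized = True
    n_records = 0
    for rec in vcf:
        n_records += 1
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ids.append(rec.ID if rec.ID is not None else ".")
        ref.append(rec.REF)
        alt.append(tuple(rec.ALT))
        aa = rec.INFO.get("AA")
        if aa != rec.REF:
            polarized = False
        try:
            gts = rec.genotypes
        except Exception:
            gts = None
        if gts is None:
            logger.warning(
                "record %s:%d has no GT field; treating all genotypes "
                "as fully missing", rec.CHROM, rec.POS)
            allele_rows.append([[MISSING, MISSING]] * len(sample_names))
            phase_rows.append([False] * len(sample_names))
            continue
        arow, prow = [], []
        for s, gt in enumerate(gts):
            if len(gt) != 3:
                raise FormatError(
                    f"non-diploid genotype for sample "
                    f"{sample_names[s]} at {rec.CHROM}:{rec.POS} "
                    f"(record {n_records}): all samples must be diploid")
            a, b, ph = gt
            arow.append([MISSING if a < 0 else a, MISSING if b < 0 else b])
            prow.append(bool(ph))
        allele_rows.append(arow)
        phase_rows.append(prow)
    vcf.close()
    if n_records == 0:
        polarized = False
    n_sites = len(chrom)
    alleles = (np.array(allele_rows, dtype=np.int16)
               if n_sites else np.empty((0, len(sample_names), 2), np.int16))
    phased = (np.array(phase_rows, dtype=bool)
              if n_sites else np.empty((0, len(sample_names)), bool))
    return GenotypeMatrix(sample_names, chrom, pos, ids, ref, alt,
                          alleles, phased, polarized=polarized)


def _render_genotype(a: int, b: int, phased: bool) -> str:
    sep = "|" if phased else "/"
    left = "." if a == MISSING else str(a)
    right = "." if b == MISSING else str(b)
    return f"{left}{sep}{right}"


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> Path:
    """Write a minimal VCF 4.2: GT-only FORMAT, contigs inferred from data.

    Phased genotypes use ``|``, unphased ``/``; missing alleles are ``.``.
    When the matrix is still polarized an ``AA=<REF>`` INFO tag records the
    ancestral allele, so downstream depolarization is observable.
    """
    path = Path(path)
    contig_max: dict[str, int] = {}
    for c, p in zip(matrix.chrom, matrix.pos):
        contig_max[c] = max(contig_max.get(c, 0), int(p))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=genodegrade {__version__}\n")
        for c, length in contig_max.items():
            fh.write(f"##contig=<ID={c},length={length}>\n")
        if matrix.polarized:
            fh.write('##INFO=<ID=AA,Number=1,Type=String,'
                     'Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_names) + "\n")
        for i in range(matrix.n_sites):
            alt = ",".join(matrix.alt[i]) if matrix.alt[i] else "."
            info = f"AA={matrix.ref[i]}" if matrix.polarized else "."
            gts = "\t".join(
                _render_genotype(int(matrix.alleles[i, s, 0]),
                                 int(matrix.alleles[i, s, 1]),
                                 bool(matrix.phased[i, s]))
                for s in range(matrix.n_samples))
            fh.write(f"{matrix.chrom[i]}\t{int(matrix.pos[i])}\t"
                     f"{matrix.ids[i]}\t{matrix.ref[i]}\t{alt}\t.\t.\t"
                     f"{info}\tGT\t{gts}\n")
    return path


# ---------------------------------------------------------------------------
# ms dialect
# ---------------------------------------------------------------------------

@dataclass
class MsReplicate:
    """One ms replicate: segregating-site count, fractional positions in
    (0, 1), and one 0/1 haplotype string per haploid chromosome."""

    segsites: int
    positions: list[float]
    haplotypes: list[str]

    def __post_init__(self) -> None:
        if len(self.positions) != self.segsites:
            raise FormatError(
                f"{len(self.positions)} positions for "
                f"segsites: {self.segsites}")
        for h in self.haplotypes:
            if len(h) != self.segsites:
                raise FormatError(
                    f"haplotype length {len(h)} != segsites {self.segsites}")
        if any(b < a for a, b in zip(self.positions, self.positions[1:])):
            raise FormatError("positions are not non-decreasing")
        if len(self.haplotypes) % 2 != 0:
            raise FormatError(
                f"odd haplotype count ({len(self.haplotypes)}): cannot "
                "pair haploid chromosomes into diploid samples")


def read_ms(path: str | os.PathLike) -> list[MsReplicate]:
    """Parse an ms-style stream into its replicates, in order."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    reps: list[MsReplicate] = []
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        # header lines of the block
        segsites = None
        positions: list[float] = []
        while i < n and lines[i].strip() != "//":
            line = lines[i].strip()
            if line.startswith("segsites:"):
                segsites = int(line.split(":", 1)[1])
                i += 1
            elif line.startswith("positions:"):
                positions = [float(t) for t in line.split(":", 1)[1].split()]
                i += 1
            elif line:
                break
            else:
                i += 1
        if segsites is None:
            raise FormatError("replicate block lacks a 'segsites:' line")
        haplotypes: list[str] = []
        if segsites > 0:
            while i < n and lines[i].strip() not in ("", "//"):
                hap = lines[i].strip()
                if not set(hap) <= {"0", "1"}:
                    raise FormatError(
                        f"haplotype row contains non-binary characters: "
                        f"{hap[:40]!r}")
                haplotypes.append(hap)
                i += 1
        reps.append(MsReplicate(segsites, positions, haplotypes))
    if not reps:
        raise FormatError("no '//' replicate delimiter found in ms input")
    return reps


def _map_positions(fractions: Sequence[float], segment_length: int
                   ) -> list[int]:
    """Map ms fractions in (0,1) onto distinct 1-based integer positions.

    A fraction f lands on floor(f * L) + 1 (a small epsilon guards against
    float round-down of exactly representable products); collisions are
    bumped upward to the next free integer, preserving order.
    """
    out: list[int] = []
    last = 0
    for f in fractions:
        p = int(math.floor(f * segment_length + 1e-9)) + 1
        if p <= last:
            p = last + 1
        out.append(p)
        last = p
    return out


def ms_to_matrix(rep: MsReplicate,
                 segment_length: int = DEFAULT_SEGMENT_LENGTH,
                 chrom_label: str = "1") -> GenotypeMatrix:
    """Convert one ms replicate to a phased, polarized genotype matrix.

    Consecutive haplotype pairs (1,2), (3,4), ... become diploid samples.
    Allele 0 is the ancestral allele and becomes REF; allele 1 the derived
    allele and becomes ALT.  Placeholder nucleotides A (REF) and T (ALT)
    are used since ms carries no sequence.
    """
    if segment_length < rep.segsites:
        raise FormatError(
            f"segment length {segment_length} < segsites {rep.segsites}: "
            "cannot place distinct integer positions")
    n_samples = len(rep.haplotypes) // 2
    sample_names = [f"sample_{k}" for k in range(1, n_samples + 1)]
    pos = _map_positions(rep.positions, segment_length)
    S = rep.segsites
    alleles = np.empty((S, n_samples, 2), dtype=np.int16)
    if S:
        hap = np.array([[int(c) for c in h] for h in rep.haplotypes],
                       dtype=np.int16)           # (2n, S)
        alleles[:, :, 0] = hap[0::2].T
        alleles[:, :, 1] = hap[1::2].T
    phased = np.ones((S, n_samples), dtype=bool)
    return GenotypeMatrix(
        sample_names, [chrom_label] * S, pos, ["."] * S,
        ["A"] * S, [("T",)] * S, alleles, phased, polarized=True)


def write_ms(matrix: GenotypeMatrix, path: str | os.PathLike,
             segment_length: int = DEFAULT_SEGMENT_LENGTH) -> Path:
    """Write a fully phased, biallelic, missing-free matrix as one ms block.

    ms output carries no representation for missing alleles or unphased
    genotypes, so either is an error here (introduce missingness only on
    the VCF path).
    """
    if matrix.n_sites and (matrix.alleles == MISSING).any():
        raise FormatError(
            "matrix contains missing alleles; ms output is only valid "
            "when no missing data has been introduced")
    if matrix.n_sites and not matrix.phased.all():
        raise FormatError("matrix contains unphased genotypes; "
                          "ms output requires full phasing")
    if not all(len(a) == 1 for a in matrix.alt):
        raise FormatError("ms output requires biallelic sites")
    path = Path(path)
    S = matrix.n_sites
    with open(path, "w") as fh:
        fh.write(f"genodegrade {2 * matrix.n_samples} 1\n\n")
        fh.write("//\n")
        fh.write(f"segsites: {S}\n")
        if S:
            fracs = " ".join(f"{(int(p) - 1) / segment_length:.8f}"
                             for p in matrix.pos)
            fh.write(f"positions: {fracs}\n")
            left = matrix.alleles[:, :, 0].T   # (n, S)
            right = matrix.alleles[:, :, 1].T
            for s in range(matrix.n_samples):
                fh.write("".join(map(str, left[s])) + "\n")
                fh.write("".join(map(str, right[s])) + "\n")
    return path


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EigenstratTriplet:
    """Paths of an EIGENSTRAT .geno/.snp/.ind triplet."""

    geno_path: Path
    snp_path: Path
    ind_path: Path


_GENO_TO_PAIR = {"0": (1, 1), "1": (0, 1), "2": (0, 0),
                 "9": (MISSING, MISSING)}


def eigenstrat_to_matrix(triplet: EigenstratTriplet) -> GenotypeMatrix:
    """Decode an EIGENSTRAT triplet into an unphased genotype matrix.

    Geno codes count REFERENCE-allele copies: 2 -> 0/0, 1 -> 0/1,
    0 -> 1/1, 9 -> ./. .  EIGENSTRAT carries no phase, so every genotype
    is unphased, and no ancestral-allele information, so the matrix is
    not polarized.
    """
    with open(triplet.ind_path) as fh:
        sample_names = [ln.split()[0] for ln in fh if ln.strip()]
    snp_rows = []
    with open(triplet.snp_path) as fh:
        for k, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            toks = ln.split()
            if len(toks) < 6:
                raise FormatError(
                    f".snp line {k}: expected 6 columns "
                    "(id chrom genetic-pos pos ref alt), got "
                    f"{len(toks)}")
            snp_rows.append((toks[0], toks[1], int(toks[3]),
                             toks[4], toks[5]))
    with open(triplet.geno_path) as fh:
        geno_lines = [ln.strip() for ln in fh if ln.strip()]
    if len(geno_lines) != len(snp_rows):
        raise FormatError(
            f".geno has {len(geno_lines)} rows but .snp has "
            f"{len(snp_rows)}")
    n = len(sample_names)
    S = len(snp_rows)
    alleles = np.empty((S, n, 2), dtype=np.int16)
    for i, row in enumerate(geno_lines):
        if len(row) != n:
            raise FormatError(
                f".geno line {i + 1} has width {len(row)} but .ind lists "
                f"{n} samples")
        for j, ch in enumerate(row):
            pair = _GENO_TO_PAIR.get(ch)
            if pair is None:
                raise FormatError(
                    f".geno line {i + 1}, column {j + 1}: invalid code "
                    f"{ch!r} (expected 0, 1, 2 or 9)")
            alleles[i, j] = pair
    phased = np.zeros((S, n), dtype=bool)
    return GenotypeMatrix(
        sample_names,
        [r[1] for r in snp_rows],
        [r[2] for r in snp_rows],
        [r[0] for r in snp_rows],
        [r[3] for r in snp_rows],
        [(r[4],) for r in snp_rows],
        alleles, phased, polarized=False)


def eigenstrat_to_vcf(triplet: EigenstratTriplet,
                      out: str | os.PathLike) -> Path:
    """Convert an EIGENSTRAT triplet straight to a VCF file."""
    return write_vcf(eigenstrat_to_matrix(triplet), out)
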