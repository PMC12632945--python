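"""Missingness summaries and histogram / KL-divergence evaluation.

``summarize_missingness`` produces per-site and per-sample missing-genotype
tables deliberately close to PLINK's .lmiss/.imiss reports, plus the
overall mean and (population) standard deviation of per-site proportions —
the two numbers that parameterize the beta missingness model.

Evaluation compares missingness *distributions*: per-site proportions are
binned into 50 equal-width bins on [0, 1] and two histograms are compared
with the Kullback–Leibler divergence KL(p ‖ q) = Σ p_i ln(p_i / q_i).
KL is undefined when q_i = 0 < p_i, so half an observation is added to
every bin of both histograms before normalizing (Jeffreys-style
pseudocount); with moderately large site counts the perturbation is
negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EmptyMatrixError, GenotypeMatrix
from .missingness import MissingnessProfile

DEFAULT_BINS = 50


@dataclass
class MissingnessSummary:
    """PLINK-style missingness report.

    ``per_site`` columns: CHROM, POS, N_MISS (fully missing), N_HALF
    (exactly one allele missing), F_MISS.  ``per_sample`` columns: SAMPLE,
    N_MISS, F_MISS.  ``overall_mean``/``overall_sd`` are the moments of
    the per-site F_MISS values (population sd).
    """

    per_site: pd.DataFrame
    per_sample: pd.DataFrame
    overall_mean: float
    overall_sd: float


def summarize_missingness(matrix: GenotypeMatrix) -> MissingnessSummary:
    if matrix.n_sites == 0 or matrix.n_samples == 0:
        raise EmptyMatrixError("cannot summarize an empty matrix")
    full = matrix.fully_missing_mask()
    half = matrix.half_missing_mask()
    n_miss_site = full.sum(axis=1)
    per_site = pd.DataFrame({
        "CHROM": matrix.chrom,
        "POS": matrix.pos,
        "N_MISS": n_miss_site,
        "N_HALF": half.sum(axis=1),
        "F_MISS": n_miss_site / matrix.n_samples,
    })
    n_miss_sample = full.sum(axis=0)
    per_sample = pd.DataFrame({
        "SAMPLE": matrix.sample_names,
        "N_MISS": n_miss_sample,
        "F_MISS": n_miss_sample / matrix.n_sites,
    })
    f = per_site["F_MISS"].to_numpy()
    return MissingnessSummary(per_site, per_sample,
                              float(f.mean()), float(f.std()))


@dataclass(frozen=True)
class MissingnessHistogram:
    """Binned distribution of per-site missing proportions on [0, 1].

    Bins are equal-width and left-closed, with the last bin right-closed
    (so a proportion of exactly 1.0 lands in the final bin).  Raw counts
    are kept so KL regularization can add fractional observations.
    """

    counts: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "edges", edges)
        if counts.size < 1 or edges.size != counts.size + 1:
            raise ValueError("need k >= 1 counts and k + 1 edges")
        if (np.diff(edges) <= 0).any():
            raise ValueError("edges must be strictly increasing")
        if (counts < 0).any() or counts.sum() <= 0:
            raise ValueError("counts must be non-negative with positive "
                             "total")

    @property
    def bin_count(self) -> int:
        return int(self.counts.size)

    @property
    def mass(self) -> np.ndarray:
        """Counts normalized to sum to 1."""
        return self.counts / self.counts.sum()


def histogram(profile: MissingnessProfile,
              bins: int = DEFAULT_BINS) -> MissingnessHistogram:
    """Bin a profile's proportions into equal-width bins over [0, 1]."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    counts, edges = np.histogram(profile.proportions, bins=bins,
                                 range=(0.0, 1.0))
    return MissingnessHistogram(counts, edges)


def kl_divergence(p: MissingnessHistogram, q: MissingnessHistogram,
                  pseudocount: float = 0.5) -> float:
    """KL(p ‖ q) in nats over matching bins, with pseudocount smoothing.

    ``pseudocount`` observations are added to every bin of both histograms
    before normalizing; the result is >= 0 and 0 iff the regularized
    distributions coincide.
    """
    if p.bin_count != q.bin_count or not np.allclose(p.edges, q.edges):
        raise ValueError("histograms have mismatched bins/edges")
    ps = p.counts + pseudocount
    qs = q.counts + pseudocount
    pm = ps / ps.sum()
    qm = qs / qs.sum()
    return float(np.sum(pm * np.log(pm / qm)))


def write_summary_tsv(summary: MissingnessSummary, site_path, sample_path
                      ) -> None:
    """Write the per-site and per-sample tables as TSV (PLINK-like)."""
    summary.per_site.to_csv(site_path, sep="\t", index=False)
    summary.per_sample.to_csv(sample_path, sep="\t", index=False)


def plot_histograms(hists: dict[str, MissingnessHistogram], path) -> None:
    """Optional side-by-side histogram plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(hists), figsize=(4 * len(hists), 3),
                             squeeze=False)
    for ax, (label, h) in zip(axes[0], hists.items()):
        centers = (h.edges[:-1] + h.edges[1:]) / 2
        ax.bar(centers, h.mass, width=np.diff(h.edges), align="center")
        ax.set_title(label)
        ax.set_xlabel("missing proportion")
        ax.set_ylabel("fraction of sites")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
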