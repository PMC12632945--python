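"""Replicating the distribution and positional dispersal of missingness.

A *template* dataset (typically an empirical ancient-DNA VCF) yields a
missingness profile x_1..x_N: the per-site proportion of samples whose
diploid genotype is fully missing.  Two engines turn a profile into target
proportions y_1..y_M for a segment of M sites:

* **Dispersal replication** preserves where along the segment missingness
  is concentrated.  For M <= N the template index range is cut into M
  contiguous blocks and y_j is a uniformly random member of block j; for
  M > N the target range is cut into N contiguous blocks and block j is
  filled with independent draws from U(min(x_j, x_{j+1}),
  max(x_j, x_{j+1})) on the half-open interval [a, b), the last block
  reusing the pair (x_{N-1}, x_N) — the pattern at the end of the template
  is assumed to extend.

* **Beta model** ignores position entirely: the profile's mean and
  standard deviation moment-match a Beta(alpha, beta) and each y_j is an
  i.i.d. draw — the conventional purely random alternative the dispersal
  method is compared against.

Both engines are deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import MISSING, EmptyMatrixError, GenotypeMatrix


@dataclass(frozen=True)
class MissingnessProfile:
    """Per-site fully-missing proportions x_1..x_N, in template site order.

    Order matters: positional dispersal is the point.
    """

    proportions: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", arr)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("profile must hold at least one proportion")
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def N(self) -> int:
        return int(self.proportions.size)


@dataclass(frozen=True)
class DispersalPlan:
    """Target per-site missing proportions y_1..y_M."""

    targets: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "targets", arr)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("plan must hold at least one target")
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("targets must lie in [0, 1]")

    @property
    def M(self) -> int:
        return int(self.targets.size)


def extract_profile(matrix: GenotypeMatrix) -> MissingnessProfile:
    """The template's missingness profile, one proportion per site."""
    if matrix.n_sites == 0:
        raise EmptyMatrixError("cannot extract a profile from an empty "
                               "matrix")
    return MissingnessProfile(matrix.missing_proportions())


def block_bounds(n: int, m: int) -> list[tuple[int, int]]:
    """Partition 0-based index range [0, n) into m contiguous blocks.

    Block j (0-based) covers [floor(j*n/m), floor((j+1)*n/m)).  For m <= n
    every block is non-empty; the partition is exhaustive and
    non-overlapping for all n, m >= 1, and reduces to equal blocks of
    n/m indices whenever m divides n.
    """
    return [(j * n // m, (j + 1) * n // m) for j in range(m)]


def replicate_dispersal(profile: MissingnessProfile, M: int,
                        rng: np.random.Generator) -> DispersalPlan:
    """Replicate the template's missingness dispersal across M target sites.

    See the module docstring for the two cases (M <= N block sampling;
    M > N interval filling).  With M == N both rules degenerate to the
    identity: the plan equals the profile exactly, for any seed.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    x = profile.proportions
    N = profile.N
    y = np.empty(M, dtype=float)
    if M <= N:
        for j, (lo, hi) in enumerate(block_bounds(N, M)):
            y[j] = x[lo + rng.integers(hi - lo)]
    elif N == 1:
        y[:] = x[0]
    else:
        for j, (lo, hi) in enumerate(block_bounds(M, N)):
            pair = (x[j], x[j + 1]) if j < N - 1 else (x[N - 2], x[N - 1])
            a, b = min(pair), max(pair)
            y[lo:hi] = a if a == b else rng.uniform(a, b, size=hi - lo)
    return DispersalPlan(y)


@dataclass(frozen=True)
class BetaMissingnessModel:
    """Beta(alpha, beta) model for per-site missing proportions.

    Parameterized by a mean and standard deviation via the method of
    moments:

        alpha = mean * (mean * (1 - mean) / sd^2 - 1)
        beta  = (1 - mean) * (mean * (1 - mean) / sd^2 - 1)

    feasible only when sd^2 < mean * (1 - mean).
    """

    mean: float
    sd: float
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.mean < 1:
            raise ValueError("mean must lie strictly in (0, 1)")
        var = self.sd ** 2
        bound = self.mean * (1 - self.mean)
        if not 0 < var < bound:
            raise ValueError(
                f"infeasible sd {self.sd}: a beta distribution with mean "
                f"{self.mean} requires 0 < sd^2 < mean*(1-mean) = "
                f"{bound:.6g}")
        nu = bound / var - 1
        object.__setattr__(self, "alpha", self.mean * nu)
        object.__setattr__(self, "beta", (1 - self.mean) * nu)


def beta_model_from_moments(mean: float, sd: float) -> BetaMissingnessModel:
    """Moment-match a beta model to a given mean and standard deviation."""
    return BetaMissingnessModel(mean=mean, sd=sd)


def beta_model_from_template(matrix: GenotypeMatrix) -> BetaMissingnessModel:
    """Fit the beta model to a template's profile moments.

    Uses the population (divide-by-N) standard deviation of the per-site
    proportions.  A zero-variance profile cannot parameterize a beta
    distribution and is an error.
    """
    profile = extract_profile(matrix)
    if profile.N < 2:
        raise ValueError("need at least 2 template sites to estimate "
                         "moments")
    x = profile.proportions
    mean = float(x.mean())
    sd = float(x.std())  # population estimator
    if sd == 0:
        raise ValueError("template profile has zero variance; beta model "
                         "is degenerate")
    return beta_model_from_moments(mean, sd)


def plan_from_beta(model: BetaMissingnessModel, M: int,
                   rng: np.random.Generator) -> DispersalPlan:
    """M i.i.d. Beta(alpha, beta) draws — the position-agnostic plan."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return DispersalPlan(rng.beta(model.alpha, model.beta, size=M))


def apply_plan(matrix: GenotypeMatrix, plan: DispersalPlan,
               rng: np.random.Generator,
               exact_count: bool = False) -> GenotypeMatrix:
    """Introduce fully-missing genotypes per the plan's proportions.

    At site j each sample independently becomes fully missing ("./.")
    with probability y_j; already-missing genotypes stay missing.  With
    ``exact_count`` the realization is instead round(y_j * n) uniformly
    chosen samples, making the realized proportion deterministic.
    Non-genotype fields are untouched.
    """
    if plan.M != matrix.n_sites:
        raise ValueError(
            f"plan length {plan.M} != matrix site count {matrix.n_sites}")
    out = matrix.copy()
    n = out.n_samples
    y = plan.targets
    if exact_count:
        for j in range(plan.M):
            k = int(round(y[j] * n))
            if k:
                idx = rng.choice(n, size=k, replace=False)
                out.alleles[j, idx] = MISSING
    else:
        hit = rng.random((plan.M, n)) < y[:, None]
        out.alleles[hit] = MISSING
    return out
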