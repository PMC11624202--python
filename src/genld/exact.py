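"""Exact sampling distribution of observed D for two unlinked loci.

In a finite random-mating sample, even unlinked loci show nonzero observed
D = p_AB - p_A p_B in almost every draw: the distribution of observed D given
the two derived allele counts is discrete and skewed, which is why set-level
LD statistics on rare variants need a finite-sample null. This module
enumerates that null exactly.

With allele counts dac1 and dac2 fixed among 2N gametes and the loci
independent, the number of derived-derived haplotypes n_AB is the only free
count; each 2x2 table (n_AB, n_Ab, n_aB, n_ab) receives probability
proportional to its multinomial coefficient (2N)! / (n_AB! n_Ab! n_aB! n_ab!),
the number of gamete orderings realizing it under random union of gametes.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial, lgamma, prod

import numpy as np

__all__ = ["TwoLocusSpec", "enumerate_unlinked_d_distribution", "diploid_table_likelihood"]

#: enumeration guard: tables are tiny, but keep the exact path honest
MAX_CHROMOSOMES = 60


@dataclass(frozen=True)
class TwoLocusSpec:
    """Two biallelic loci in a diploid sample of N individuals.

    ``dac1`` and ``dac2`` are the derived allele counts among the 2N gametes;
    both loci must be polymorphic (1 <= dac <= 2N - 1).
    """

    n_individuals: int
    dac1: int
    dac2: int

    def __post_init__(self) -> None:
        two_n = 2 * self.n_individuals
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        for dac in (self.dac1, self.dac2):
            if not 1 <= dac <= two_n - 1:
                raise ValueError(f"dac={dac} out of polymorphic range [1, {two_n - 1}]")

    @property
    def two_n(self) -> int:
        return 2 * self.n_individuals


def enumerate_unlinked_d_distribution(spec: TwoLocusSpec) -> list[tuple[float, float]]:
    """All (D, probability) pairs for unlinked loci with fixed allele counts.

    Enumerates every haplotype table with the given margins; probabilities are
    normalized multinomial weights (equivalently, n_AB is hypergeometric).
    Entries with equal D are merged; probabilities sum to 1 and E[D] = 0.
    """
    two_n = spec.two_n
    if two_n > MAX_CHROMOSOMES:
        raise ValueError(
            f"2N = {two_n} exceeds the enumeration guard ({MAX_CHROMOSOMES} chromosomes)"
        )
    k_min = max(0, spec.dac1 + spec.dac2 - two_n)
    k_max = min(spec.dac1, spec.dac2)
    weights = []
    d_values = []
    for k in range(k_min, k_max + 1):
        counts = (k, spec.dac1 - k, spec.dac2 - k, two_n - spec.dac1 - spec.dac2 + k)
        log_w = lgamma(two_n + 1) - sum(lgamma(c + 1) for c in counts)
        weights.append(log_w)
        d_values.append(k / two_n - (spec.dac1 / two_n) * (spec.dac2 / two_n))
    weights = np.asarray(weights)
    probs = np.exp(weights - weights.max())
    probs /= probs.sum()
    # D is strictly increasing in n_AB, so per-k entries are already distinct
    return [(float(d), float(p)) for d, p in zip(d_values, probs)]


def diploid_table_likelihood(y: np.ndarray, counts: np.ndarray) -> tuple[float, int]:
    """Likelihood and combination number of a 3x3 diploid two-locus table.

    ``y`` holds the nine two-locus genotype-class frequencies and ``counts``
    the observed class counts N_ij over the N = sum(counts) individuals.
    Returns ``(prod y_ij**N_ij, (2N)! / prod N_ij!)`` — the per-table
    likelihood and the printed combination number for a user-supplied
    frequency vector.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    counts = np.asarray(counts, dtype=int).reshape(-1)
    if y.shape != (9,) or counts.shape != (9,):
        raise ValueError("y and counts must each have nine entries (3x3 classes)")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    likelihood = prod(float(f) ** int(c) for f, c in zip(y, counts))
    n_total = int(counts.sum())
    combination = factorial(2 * n_total)
    for c in counts:
        combination //= factorial(int(c))
    return likelihood, combination
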