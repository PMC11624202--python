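"""Frequency-spectrum-matched resampling and permutation p-values.

LD statistics depend strongly on the allele frequency spectrum, so a target
set (e.g. LoF variants) cannot be compared to a null pool (e.g. synonymous
variants) directly: null replicate sets are drawn from the pool with exactly
the target's derived-allele-count histogram, stratum by stratum, and the
observed statistic is ranked against the replicates with the add-one
permutation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import LocusSet

__all__ = ["ResamplingPlan", "daf_matched_resample", "permutation_pvalue"]


@dataclass(frozen=True)
class ResamplingPlan:
    """How to draw frequency-matched null sets.

    ``match_on="dac"`` matches the exact derived allele count histogram;
    ``match_on="daf_bin"`` relaxes to ``n_bins`` equal-width frequency bins,
    useful when the pool is too small for exact count matching.
    """

    n_reps: int = 100
    seed: int | None = None
    match_on: str = "dac"
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.match_on not in ("dac", "daf_bin"):
            raise ValueError("match_on must be 'dac' or 'daf_bin'")


def _strata(locus_set: LocusSet, plan: ResamplingPlan) -> np.ndarray:
    if plan.match_on == "dac":
        return locus_set.dac
    two_n = 2 * locus_set.source.n_individuals
    edges = np.linspace(0.0, 1.0, plan.n_bins + 1)
    return np.clip(np.digitize(locus_set.dac / two_n, edges[1:-1]), 0, plan.n_bins - 1)


def daf_matched_resample(
    pool: LocusSet, target: LocusSet, plan: ResamplingPlan | None = None
) -> list[LocusSet]:
    """Draw null sets from ``pool`` matching ``target``'s frequency spectrum.

    Each replicate draws, without replacement and independently of the other
    replicates, exactly as many pool loci in every dac stratum as the target
    holds there. Raises if any stratum of the pool is too small, naming the
    stratum and the shortfall.
    """
    plan = plan or ResamplingPlan()
    if pool.source is not target.source:
        raise ValueError("pool and target must index the same genotype matrix")
    pool_strata = _strata(pool, plan)
    target_strata = _strata(target, plan)
    wanted_vals, wanted_counts = np.unique(target_strata, return_counts=True)
    pool_by_stratum: dict[int, np.ndarray] = {}
    for val, want in zip(wanted_vals.tolist(), wanted_counts.tolist()):
        members = pool.indices[pool_strata == val]
        if len(members) < want:
            raise ValueError(
                f"pool has {len(members)} loci in stratum {plan.match_on}={val}, "
                f"target needs {want} (shortfall {want - len(members)})"
            )
        pool_by_stratum[val] = members
    rng = np.random.default_rng(plan.seed)
    replicates = []
    for rep in range(plan.n_reps):
        chosen = [
            rng.choice(pool_by_stratum[val], size=want, replace=False)
            for val, want in zip(wanted_vals.tolist(), wanted_counts.tolist())
        ]
        indices = np.sort(np.concatenate(chosen))
        replicates.append(
            LocusSet(
                source=pool.source,
                indices=indices,
                label=f"{pool.label}~{target.label}[{rep}]",
                mdac=target.mdac,
                mdaf=target.mdaf,
            )
        )
    return replicates


def permutation_pvalue(observed: float, null_values, side: str = "two") -> float:
    """Add-one permutation p-value of ``observed`` against null replicates.

    ``lower``: P(null <= observed); ``upper``: P(null >= observed); ``two``:
    2 * min(lower, upper) capped at 1. The add-one rule ((1 + hits)/(R + 1))
    keeps p-values in (0, 1].
    """
    nulls = np.asarray(list(null_values), dtype=float)
    if nulls.size == 0:
        raise ValueError("need at least one null value")
    r = nulls.size
    lower = (1 + int(np.sum(nulls <= observed))) / (r + 1)
    upper = (1 + int(np.sum(nulls >= observed))) / (r + 1)
    if side == "lower":
        return float(lower)
    if side == "upper":
        return float(upper)
    if side == "two":
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError("side must be 'lower', 'upper' or 'two'")
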