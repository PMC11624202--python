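"""Pairwise LD statistics on derived-allele dosages and haplotypes.

The central statistics are set-level means over all admissible locus pairs
``i < j`` of a locus set L:

* ``LDcor``      — mean Pearson correlation of dosage vectors, in [-1, 1].
  Signed: coupling LD (derived alleles co-occurring in the same individuals)
  pushes it positive, repulsion LD pushes it negative, and the two can cancel.
* ``LDcorabs``   — mean absolute correlation, in [0, 1]; zero iff all loci are
  pairwise uncorrelated, so cancellation cannot hide LD.
* ``NetLD``      — mean raw (unstandardized) covariance of dosages.
* ``nLDcor(abs)``— difference between a target set (e.g. LoF) and a null set
  (e.g. synonymous), making values comparable across datasets.

All of these need only unphased genotypes. Classical haplotype-based measures
(D, D', r², signed sqrt(r²)) are provided for comparison and validation when
phase is known.

Conventions: sample moments with the n-1 denominator throughout (correlations
are denominator-invariant; NetLD and V_A are not, and the convention is
recorded in results). The pair-average prefactor divides by the number of
locus pairs m(m-1)/2, which keeps LDcor in [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import LocusSet

__all__ = [
    "PairFilter",
    "LDResult",
    "HaplotypeCounts",
    "dosage_correlation",
    "ldcor",
    "ldcorabs",
    "netld",
    "v_over_va",
    "nldcor",
    "nldcorabs",
    "classical_two_locus",
    "signed_sqrt_r2_mean",
]

#: above this many pairs, ldcorabs falls back to seeded uniform subsampling
DEFAULT_MAX_PAIRS = 5_000_000


class ZeroVarianceError(ValueError):
    """A constant dosage vector has no defined correlation."""


@dataclass(frozen=True)
class PairFilter:
    """Restricts which locus pairs enter a set-level LD average.

    Cross-chromosome pairs count as infinitely distant: they are admitted by
    any ``min_distance_bp``, excluded by any finite ``max_distance_bp``, and
    excluded entirely when ``same_chrom_only`` is set.
    """

    min_distance_bp: float = 0.0
    max_distance_bp: float | None = None
    same_chrom_only: bool = False

    def __post_init__(self) -> None:
        if self.max_distance_bp is not None and self.min_distance_bp > self.max_distance_bp:
            raise ValueError("min_distance_bp must be <= max_distance_bp")

    @property
    def admits_all(self) -> bool:
        return (
            self.min_distance_bp <= 0
            and self.max_distance_bp is None
            and not self.same_chrom_only
        )

    def pair_mask(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean (m, m) strict-upper-triangle mask of admissible pairs."""
        m = len(pos)
        pos = np.asarray(pos, dtype=float)
        chrom = np.asarray(chrom)
        same = chrom[:, None] == chrom[None, :]
        dist = np.abs(pos[:, None] - pos[None, :])
        dist = np.where(same, dist, np.inf)
        ok = dist >= self.min_distance_bp
        if self.max_distance_bp is not None:
            ok &= dist <= self.max_distance_bp
        if self.same_chrom_only:
            ok &= same
        return np.triu(ok, k=1)


@dataclass
class LDResult:
    """One set-level LD statistic plus the provenance needed to compare it."""

    statistic: str
    value: float
    n_loci: int
    n_pairs: int
    set_label: str = "custom"
    pair_filter: PairFilter = field(default_factory=PairFilter)
    computation_path: str = "exact"  # fast | exact | subsampled
    moment_denominator: str = "n-1"

    def to_row(self) -> dict:
        return {
            "set": self.set_label,
            "statistic": self.statistic,
            "value": self.value,
            "n_loci": self.n_loci,
            "n_pairs": self.n_pairs,
            "min_distance_bp": self.pair_filter.min_distance_bp,
            "max_distance_bp": self.pair_filter.max_distance_bp,
            "same_chrom_only": self.pair_filter.same_chrom_only,
            "path": self.computation_path,
        }


def _standardize(X: np.ndarray) -> np.ndarray:
    """Columns centred and scaled to unit sample (ddof=1) variance."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ZeroVarianceError(f"locus column {bad} is constant (zero variance)")
    return (X - X.mean(axis=0)) / sd


def dosage_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two dosage vectors, the per-pair LD term.

    Raises :class:`ZeroVarianceError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 2")
    Z = _standardize(np.column_stack([x, y]))
    return float(Z[:, 0] @ Z[:, 1] / (len(x) - 1))


def _resolve_mask(locus_set: LocusSet, pf: PairFilter) -> np.ndarray | None:
    """None means every pair is admissible (fast paths allowed)."""
    if pf.admits_all:
        return None
    loci = locus_set.loci
    return pf.pair_mask(loci["chrom"].to_numpy(), loci["pos"].to_numpy())


def ldcor(locus_set: LocusSet, pair_filter: PairFilter | None = None) -> LDResult:
    """Mean pairwise dosage correlation (LDcor) over a locus set.

    When the pair filter admits every pair, the O(m^2) pair sum collapses via
    the variance identity ``Var(sum_j Z_j) = m + 2 * sum_{i<j} cor(X_i, X_j)``
    on unit-standardized columns ``Z_j`` — cost linear in ``n * m``. Otherwise
    the admissible pairs are averaged explicitly.
    """
    pf = pair_filter or PairFilter()
    locus_set.require_pairs()
    Z = _standardize(locus_set.dosages)
    n, m = Z.shape
    mask = _resolve_mask(locus_set, pf)
    if mask is None:
        var_sum = Z.sum(axis=1).var(ddof=1)
        pair_sum = (var_sum - m) / 2.0
        n_pairs = m * (m - 1) // 2
        path = "fast"
    else:
        n_pairs = int(mask.sum())
        if n_pairs == 0:
            raise ValueError("pair filter excludes every locus pair")
        C = (Z.T @ Z) / (n - 1)
        pair_sum = float(C[mask].sum())
        path = "exact"
    return LDResult(
        statistic="ldcor",
        value=float(pair_sum / n_pairs),
        n_loci=m,
        n_pairs=n_pairs,
        set_label=locus_set.label,
        pair_filter=pf,
        computation_path=path,
    )


def ldcorabs(
    locus_set: LocusSet,
    pair_filter: PairFilter | None = None,
    max_pairs: int | None = DEFAULT_MAX_PAIRS,
    seed: int | None = None,
) -> LDResult:
    """Mean absolute pairwise dosage correlation (LDcorabs).

    The absolute value breaks the variance identity, so pairs are iterated.
    Beyond ``max_pairs`` admissible pairs, a seeded uniform subsample of pairs
    (without replacement) is averaged instead and the result is flagged
    ``subsampled``.
    """
    pf = pair_filter or PairFilter()
    locus_set.require_pairs()
    Z = _standardize(locus_set.dosages)
    n, m = Z.shape
    mask = _resolve_mask(locus_set, pf)
    if mask is None:
        n_admissible = m * (m - 1) // 2
    else:
        n_admissible = int(mask.sum())
        if n_admissible == 0:
            raise ValueError("pair filter excludes every locus pair")

    if max_pairs is not None and n_admissible > max_pairs:
        rng = np.random.default_rng(seed)
        if mask is None:
            iu = np.triu_indices(m, k=1)
        else:
            iu = np.nonzero(mask)
        take = rng.choice(n_admissible, size=max_pairs, replace=False)
        ii, jj = iu[0][take], iu[1][take]
        total = 0.0
        for start in range(0, len(ii), 262_144):
            sl = slice(start, start + 262_144)
            total += np.abs(
                np.einsum("ni,ni->i", Z[:, ii[sl]], Z[:, jj[sl]]) / (n - 1)
            ).sum()
        return LDResult(
            statistic="ldcorabs",
            value=float(total / max_pairs),
            n_loci=m,
            n_pairs=max_pairs,
            set_label=locus_set.label,
            pair_filter=pf,
            computation_path="subsampled",
        )

    C = np.abs((Z.T @ Z) / (n - 1))
    if mask is None:
        pair_sum = float(np.triu(C, k=1).sum())
    else:
        pair_sum = float(C[mask].sum())
    return LDResult(
        statistic="ldcorabs",
        value=float(pair_sum / n_admissible),
        n_loci=m,
        n_pairs=n_admissible,
        set_label=locus_set.label,
        pair_filter=pf,
        computation_path="exact",
    )


def netld(locus_set: LocusSet, pair_filter: PairFilter | None = None) -> LDResult:
    """Mean pairwise raw covariance of dosages (NetLD), n-1 denominator.

    Computed through ``Var(sum_j X_j) = sum_j Var(X_j) + 2 sum_{i<j} cov`` when
    all pairs are admissible.
    """
    pf = pair_filter or PairFilter()
    locus_set.require_pairs()
    X = np.asarray(locus_set.dosages, dtype=float)
    n, m = X.shape
    mask = _resolve_mask(locus_set, pf)
    if mask is None:
        pair_sum = (X.sum(axis=1).var(ddof=1) - X.var(axis=0, ddof=1).sum()) / 2.0
        n_pairs = m * (m - 1) // 2
        path = "fast"
    else:
        n_pairs = int(mask.sum())
        if n_pairs == 0:
            raise ValueError("pair filter excludes every locus pair")
        Xc = X - X.mean(axis=0)
        C = (Xc.T @ Xc) / (n - 1)
        pair_sum = float(C[mask].sum())
        path = "exact"
    return LDResult(
        statistic="netld",
        value=float(pair_sum / n_pairs),
        n_loci=m,
        n_pairs=n_pairs,
        set_label=locus_set.label,
        pair_filter=pf,
        computation_path=path,
    )


def v_over_va(locus_set: LocusSet) -> dict[str, float]:
    """Ratio of the variance of the summed burden to the additive variance.

    Two variants are reported because they differ on the covariance term:

    * ``compact_form`` — ``(m(m-1)/2 * NetLD + V_A) / V_A`` with m the number
      of loci, i.e. the covariance sum entering once;
    * ``direct_ratio``  — ``Var(sum_j X_j) / sum_j Var(X_j)`` computed from the
      data, where the covariance sum enters twice
      (``Var(sum) = V_A + 2 * sum_{i<j} cov``).
    """
    locus_set.require_pairs()
    X = np.asarray(locus_set.dosages, dtype=float)
    m = X.shape[1]
    v_a = X.var(axis=0, ddof=1).sum()
    if v_a == 0:
        raise ZeroVarianceError("additive variance V_A is zero")
    net = netld(locus_set).value
    return {
        "compact_form": float((m * (m - 1) / 2.0 * net + v_a) / v_a),
        "direct_ratio": float(X.sum(axis=1).var(ddof=1) / v_a),
    }


def _normalized_difference(target: LDResult, null: LDResult, statistic: str) -> float:
    for r, name in ((target, "target"), (null, "null")):
        if r.statistic != statistic:
            raise ValueError(f"{name} result holds '{r.statistic}', expected '{statistic}'")
    if target.pair_filter != null.pair_filter:
        raise ValueError("target and null were computed under different pair filters")
    return float(target.value - null.value)


def nldcor(target: LDResult, null: LDResult) -> float:
    """LDcor of the target set minus LDcor of the null set (range [-2, 2])."""
    return _normalized_difference(target, null, "ldcor")


def nldcorabs(target: LDResult, null: LDResult) -> float:
    """LDcorabs difference between a target and a null set."""
    return _normalized_difference(target, null, "ldcorabs")


# -- classical haplotype-based statistics -------------------------------------


@dataclass(frozen=True)
class HaplotypeCounts:
    """Two-locus haplotype counts over 2N gametes (A/a at locus 1, B/b at 2).

    A and B denote the derived alleles, so the sign of D follows the
    derived-derived coupling convention.
    """

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    def __post_init__(self) -> None:
        if min(self.n_AB, self.n_Ab, self.n_aB, self.n_ab) < 0:
            raise ValueError("haplotype counts must be nonnegative")
        if self.total < 1:
            raise ValueError("total haplotype count must be >= 1")

    @property
    def total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    @property
    def p_AB(self) -> float:
        return self.n_AB / self.total

    @property
    def p_A(self) -> float:
        return (self.n_AB + self.n_Ab) / self.total

    @property
    def p_B(self) -> float:
        return (self.n_AB + self.n_aB) / self.total


def classical_two_locus(h: HaplotypeCounts) -> dict[str, float]:
    """D, D', r² and signed sqrt(r²) from a 2x2 haplotype table.

    ``D = p_AB - p_A p_B``; ``r² = D² / (p_A p_a p_B p_b)``; D' normalizes D by
    ``max(-p_A p_B, -p_a p_b)`` when D < 0 and by ``min(p_A p_b, p_a p_B)``
    when D > 0 (D = 0 gives D' = 0). Both loci must be polymorphic.
    """
    p_A, p_B = h.p_A, h.p_B
    p_a, p_b = 1.0 - p_A, 1.0 - p_B
    if min(p_A, p_a, p_B, p_b) <= 0:
        raise ZeroVarianceError("both loci must be polymorphic (frequencies in (0,1))")
    D = h.p_AB - p_A * p_B
    r2 = D * D / (p_A * p_a * p_B * p_b)
    if D < 0:
        d_prime = D / max(-p_A * p_B, -p_a * p_b)
    elif D > 0:
        d_prime = D / min(p_A * p_b, p_a * p_B)
    else:
        d_prime = 0.0
    return {
        "D": float(D),
        "D_prime": float(d_prime),
        "r2": float(r2),
        "signed_sqrt_r2": float(math.copysign(math.sqrt(r2), D)) if D != 0 else 0.0,
    }


def signed_sqrt_r2_mean(
    haplotypes: np.ndarray,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    pair_filter: PairFilter | None = None,
) -> float:
    """Mean of sign(D)·sqrt(r²) over locus pairs of a phased haplotype matrix.

    ``haplotypes`` is ``(2n, m)`` binary with 1 = derived allele; this is the
    phased-data comparison oracle for LDcor. For one pair,
    sign(D)·sqrt(r²) = D / sqrt(p_A p_a p_B p_b), the correlation of the two
    haplotype indicator columns.
    """
    H = np.asarray(haplotypes)
    if H.ndim != 2 or (H.size and not np.isin(H, (0, 1)).all()):
        raise ValueError("haplotypes must be a 2-D binary (0/1 phased) matrix")
    H = H.astype(float)
    m = H.shape[1]
    if m < 2:
        raise ValueError("need >= 2 loci")
    p = H.mean(axis=0)
    if np.any((p <= 0) | (p >= 1)):
        raise ZeroVarianceError("all loci must be polymorphic in the haplotype sample")
    P = (H.T @ H) / H.shape[0]
    D = P - np.outer(p, p)
    sd = np.sqrt(p * (1.0 - p))
    S = D / np.outer(sd, sd)
    pf = pair_filter or PairFilter()
    if pf.admits_all:
        mask = np.triu(np.ones((m, m), dtype=bool), k=1)
    else:
        if chrom is None or pos is None:
            raise ValueError("chrom and pos are required under a distance filter")
        mask = pf.pair_mask(np.asarray(chrom), np.asarray(pos))
        if not mask.any():
            raise ValueError("pair filter excludes every locus pair")
    return float(S[mask].mean())
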