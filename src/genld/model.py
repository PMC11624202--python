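"""Model/Results front end tying ingestion, LD statistics and inference together.

``UnphasedLD`` is the estimation entry point most analyses want: point it at a
genotype matrix (or a VCF plus ancestral / annotation inputs), name a target
category (e.g. LoF) and a null category (e.g. synonymous), and ``fit()``
returns an :class:`UnphasedLDResults` carrying LDcor, LDcorabs, NetLD and
V/V_A for both sets, the normalized differences nLDcor / nLDcorabs, and
permutation p-values against frequency-matched null resamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ldstats
from .ldstats import LDResult, PairFilter
from .matrix import GenotypeMatrix, LocusSet
from .resampling import ResamplingPlan, daf_matched_resample, permutation_pvalue
from .vcfio import (
    AncestralMap,
    annotations_from_tsv,
    annotations_from_vcf_csq,
    apply_annotations,
    polarize_to_derived,
    read_vcf_genotypes,
    select_locus_set,
)

__all__ = ["UnphasedLD", "UnphasedLDResults"]


class UnphasedLD:
    """Global LD of a target variant class, measured on unphased genotypes.

    Parameters
    ----------
    genotypes
        Derived-allele dosage matrix (polarized).
    target, null
        Category labels present in the matrix annotation (or ready-made
        :class:`LocusSet` objects). ``null=None`` skips normalization and
        permutation inference.
    mdac, mdaf, min_dac
        Frequency conditioning applied to both sets so their spectra are
        comparable; ``min_dac`` defaults to 2 (doubletons and up).
    pair_filter
        Optional distance restriction on admissible locus pairs.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        target: str | LocusSet = "LoF",
        null: str | LocusSet | None = "synonymous",
        mdac: int | None = None,
        mdaf: float | None = None,
        min_dac: int = 2,
        pair_filter: PairFilter | None = None,
    ):
        self.genotypes = genotypes
        self.pair_filter = pair_filter or PairFilter()
        self.mdac, self.mdaf, self.min_dac = mdac, mdaf, min_dac
        self.target_set = self._resolve(target)
        self.null_set = self._resolve(null) if null is not None else None

    def _resolve(self, spec: str | LocusSet) -> LocusSet:
        if isinstance(spec, LocusSet):
            return spec
        return select_locus_set(
            self.genotypes, spec, mdac=self.mdac, mdaf=self.mdaf, min_dac=self.min_dac
        )

    @classmethod
    def from_vcf(
        cls,
        vcf_path: str | Path,
        ancestral: str | Path | AncestralMap | None = None,
        annotations: str | Path | dict | None = None,
        target: str = "LoF",
        null: str | None = "synonymous",
        read_kwargs: dict | None = None,
        **kwargs,
    ) -> "UnphasedLD":
        """Build the model straight from a VCF.

        ``ancestral`` may be a chrom/pos/allele TSV path, an
        :class:`AncestralMap`, or None to use the VCF's ``AA`` INFO tags.
        ``annotations`` may be a chrom/pos/category TSV path, a mapping, or
        None to parse a VEP-style ``CSQ`` INFO field.
        """
        gm = read_vcf_genotypes(vcf_path, **(read_kwargs or {}))
        if isinstance(ancestral, AncestralMap):
            aa = ancestral
        elif ancestral is not None:
            aa = AncestralMap.from_tsv(ancestral)
        else:
            aa = AncestralMap.from_vcf(vcf_path)
        gm = polarize_to_derived(gm, aa)
        if isinstance(annotations, dict):
            ann = annotations
        elif annotations is not None:
            ann = annotations_from_tsv(annotations)
        else:
            ann = annotations_from_vcf_csq(vcf_path)
        gm = apply_annotations(gm, ann)
        return cls(gm, target=target, null=null, **kwargs)

    def fit(
        self,
        n_resamples: int = 100,
        seed: int | None = None,
        max_pairs: int | None = ldstats.DEFAULT_MAX_PAIRS,
    ) -> "UnphasedLDResults":
        """Compute all statistics and, when a null set exists, permutation
        p-values of the target against ``n_resamples`` frequency-matched
        null sets (0 disables resampling)."""
        pf = self.pair_filter
        target_stats = {
            "ldcor": ldstats.ldcor(self.target_set, pf),
            "ldcorabs": ldstats.ldcorabs(self.target_set, pf, max_pairs=max_pairs, seed=seed),
            "netld": ldstats.netld(self.target_set, pf),
        }
        target_v = ldstats.v_over_va(self.target_set)
        null_stats = None
        null_v = None
        nldcor = nldcorabs = None
        null_distributions: dict[str, np.ndarray] = {}
        pvalues: dict[str, dict[str, float]] = {}
        if self.null_set is not None:
            null_stats = {
                "ldcor": ldstats.ldcor(self.null_set, pf),
                "ldcorabs": ldstats.ldcorabs(self.null_set, pf, max_pairs=max_pairs, seed=seed),
                "netld": ldstats.netld(self.null_set, pf),
            }
            null_v = ldstats.v_over_va(self.null_set)
            nldcor = ldstats.nldcor(target_stats["ldcor"], null_stats["ldcor"])
            nldcorabs = ldstats.nldcorabs(target_stats["ldcorabs"], null_stats["ldcorabs"])
            if n_resamples > 0:
                plan = ResamplingPlan(n_reps=n_resamples, seed=seed)
                replicates = daf_matched_resample(self.null_set, self.target_set, plan)
                for stat in ("ldcor", "ldcorabs"):
                    fn = getattr(ldstats, stat)
                    nulls = np.array([fn(rep, pf).value for rep in replicates])
                    null_distributions[stat] = nulls
                    obs = target_stats[stat].value
                    pvalues[stat] = {
                        side: permutation_pvalue(obs, nulls, side)
                        for side in ("lower", "upper", "two")
                    }
        return UnphasedLDResults(
            model=self,
            target_stats=target_stats,
            null_stats=null_stats,
            target_v_over_va=target_v,
            null_v_over_va=null_v,
            nldcor=nldcor,
            nldcorabs=nldcorabs,
            null_distributions=null_distributions,
            pvalues=pvalues,
            n_resamples=n_resamples if self.null_set is not None else 0,
            seed=seed,
        )


@dataclass
class UnphasedLDResults:
    """Fitted LD statistics with resampling-based uncertainty."""

    model: UnphasedLD
    target_stats: dict[str, LDResult]
    null_stats: dict[str, LDResult] | None
    target_v_over_va: dict[str, float]
    null_v_over_va: dict[str, float] | None
    nldcor: float | None
    nldcorabs: float | None
    null_distributions: dict[str, np.ndarray] = field(default_factory=dict)
    pvalues: dict[str, dict[str, float]] = field(default_factory=dict)
    n_resamples: int = 0
    seed: int | None = None

    @property
    def ldcor(self) -> float:
        return self.target_stats["ldcor"].value

    @property
    def ldcorabs(self) -> float:
        return self.target_stats["ldcorabs"].value

    @property
    def netld(self) -> float:
        return self.target_stats["netld"].value

    def to_frame(self) -> pd.DataFrame:
        """One row per (set, statistic), the TSV-ready report."""
        rows = [r.to_row() for r in self.target_stats.values()]
        if self.null_stats is not None:
            rows += [r.to_row() for r in self.null_stats.values()]
        df = pd.DataFrame(rows)
        extra = []
        if self.nldcor is not None:
            extra.append(
                {"set": self.model.target_set.label, "statistic": "nldcor", "value": self.nldcor}
            )
            extra.append(
                {
                    "set": self.model.target_set.label,
                    "statistic": "nldcorabs",
                    "value": self.nldcorabs,
                }
            )
        for stat, dist in self.null_distributions.items():
            extra.append(
                {
                    "set": self.model.target_set.label,
                    "statistic": f"{stat}_null_mean",
                    "value": float(dist.mean()),
                }
            )
            extra.append(
                {
                    "set": self.model.target_set.label,
                    "statistic": f"{stat}_null_sd",
                    "value": float(dist.std(ddof=1)) if len(dist) > 1 else np.nan,
                }
            )
        for stat, sides in self.pvalues.items():
            for side, p in sides.items():
                extra.append(
                    {
                        "set": self.model.target_set.label,
                        "statistic": f"{stat}_p_{side}",
                        "value": p,
                    }
                )
        return pd.concat([df, pd.DataFrame(extra)], ignore_index=True) if extra else df

    def summary(self) -> str:
        """Human-readable fit report."""
        t = self.model.target_set
        lines = [
            "Unphased-genotype linkage disequilibrium",
            "=" * 56,
            f"individuals: {self.model.genotypes.n_individuals:>8d}"
            f"    min_dac: {self.model.min_dac}"
            f"    mdac: {self.model.mdac}    mdaf: {self.model.mdaf}",
            f"target set '{t.label}': {len(t)} loci",
        ]
        if self.null_stats is not None:
            n = self.model.null_set
            lines.append(f"null   set '{n.label}': {len(n)} loci")
        lines.append("-" * 56)
        lines.append(f"{'statistic':<12}{'target':>14}" + (f"{'null':>14}" if self.null_stats else ""))
        for stat in ("ldcor", "ldcorabs", "netld"):
            row = f"{stat:<12}{self.target_stats[stat].value:>14.6g}"
            if self.null_stats is not None:
                row += f"{self.null_stats[stat].value:>14.6g}"
            lines.append(row)
        row = f"{'V/V_A':<12}{self.target_v_over_va['compact_form']:>14.6g}"
        if self.null_v_over_va is not None:
            row += f"{self.null_v_over_va['compact_form']:>14.6g}"
        lines.append(row)
        if self.nldcor is not None:
            lines.append("-" * 56)
            lines.append(f"{'nldcor':<12}{self.nldcor:>14.6g}")
            lines.append(f"{'nldcorabs':<12}{self.nldcorabs:>14.6g}")
        if self.pvalues:
            lines.append("-" * 56)
            lines.append(f"permutation p-values ({self.n_resamples} matched resamples, add-one):")
            for stat, sides in self.pvalues.items():
                lines.append(
                    f"  {stat:<10} lower={sides['lower']:.4g}  "
                    f"upper={sides['upper']:.4g}  two={sides['two']:.4g}"
                )
        return "\n".join(lines)
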