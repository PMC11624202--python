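"""Core containers: derived-allele dosage matrices, locus sets, ancestral maps.

The whole package computes on one in-memory object, the :class:`GenotypeMatrix`:
an ``n_individuals x n_loci`` matrix of derived-allele dosages (0, 1 or 2 copies
per diploid individual) plus a per-locus metadata table. Locus sets
(:class:`LocusSet`) are ordered index subsets of a matrix — the functional
categories (synonymous / missense / LoF) and frequency-conditioned sets every
LD statistic is averaged over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "LocusSet", "AncestralMap", "InsufficientLociError"]

#: severity ranking used when one site carries several functional annotations
CATEGORY_SEVERITY = {"LoF": 3, "missense": 2, "synonymous": 1}

#: VEP-style consequence terms collapsed into the LoF category: premature stop,
#: lost stop, and disruption of the 2-bp intronic splice motifs.
LOF_CONSEQUENCES = frozenset(
    {"stop_gained", "stop_lost", "splice_acceptor_variant", "splice_donor_variant"}
)


class InsufficientLociError(ValueError):
    """Raised when a locus set is too small for any pairwise LD computation."""


@dataclass
class GenotypeMatrix:
    """Diploid derived-allele dosages for ``n`` individuals at ``m`` loci.

    Parameters
    ----------
    dosages
        ``(n, m)`` integer array with entries in ``{0, 1, 2}`` counting copies
        of the derived (or, before polarization, the ALT) allele. No missing
        entries: sites with missing calls are excluded at read time.
    loci
        Per-locus metadata with at least ``chrom``, ``pos`` (1-based bp) and
        ``dac`` (derived allele count, the column sum). Optional columns:
        ``category`` (functional label) and ``s`` (selection coefficient, for
        simulated data).
    sample_ids
        One identifier per row.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x loci) array")
        if self.dosages.size and not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2} with no missing entries")
        self.loci = self.loci.reset_index(drop=True)
        if len(self.loci) != self.dosages.shape[1]:
            raise ValueError("loci table length must equal the number of columns")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(self.dosages.shape[0])]
        if "dac" not in self.loci.columns:
            self.loci["dac"] = self.dosages.sum(axis=0).astype(int)
        else:
            stored = np.asarray(self.loci["dac"], dtype=int)
            if self.dosages.size and not np.array_equal(stored, self.dosages.sum(axis=0)):
                raise ValueError("stored dac does not match dosage column sums")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def dac(self) -> np.ndarray:
        """Derived allele count per locus (column sums)."""
        return np.asarray(self.loci["dac"], dtype=int)

    @property
    def daf(self) -> np.ndarray:
        """Derived allele frequency per locus, out of 2n chromosomes."""
        return self.dac / (2 * self.n_individuals)

    def take_loci(self, indices: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given locus columns (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            loci=self.loci.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def drop_monomorphic(self) -> "GenotypeMatrix":
        """Drop columns fixed (dac == 2n) or lost (dac == 0) in this sample."""
        dac = self.dac
        keep = np.flatnonzero((dac >= 1) & (dac <= 2 * self.n_individuals - 1))
        return self.take_loci(keep)

    # -- plain-text round trip ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV: metadata columns then one dosage column per sample."""
        out = self.loci.copy()
        for i, sid in enumerate(self.sample_ids):
            out[f"gt:{sid}"] = self.dosages[i, :]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        gt_cols = [c for c in df.columns if c.startswith("gt:")]
        sample_ids = [c[3:] for c in gt_cols]
        dosages = np.ascontiguousarray(df[gt_cols].to_numpy(dtype=np.int8).T)
        loci = df.drop(columns=gt_cols)
        return cls(dosages=dosages, loci=loci, sample_ids=sample_ids)


@dataclass
class LocusSet:
    """An ordered subset of loci of a :class:`GenotypeMatrix`.

    Names the locus sets the LD statistics average over: a deleterious target
    set (e.g. LoF) or a near-neutral null set (synonymous), optionally
    conditioned on a maximum derived allele count (``mdac``) or frequency
    (``mdaf``) so that spectra are comparable between sets.
    """

    source: GenotypeMatrix
    indices: np.ndarray
    label: str = "custom"
    mdac: int | None = None
    mdaf: float | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("locus set indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def dosages(self) -> np.ndarray:
        """(n_individuals, len(self)) dosage submatrix."""
        return self.source.dosages[:, self.indices]

    @property
    def dac(self) -> np.ndarray:
        return self.source.dac[self.indices]

    @property
    def loci(self) -> pd.DataFrame:
        return self.source.loci.iloc[self.indices]

    def dac_histogram(self) -> dict[int, int]:
        vals, counts = np.unique(self.dac, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def require_pairs(self) -> None:
        if len(self) < 2:
            raise InsufficientLociError(
                f"locus set '{self.label}' has {len(self)} loci; >= 2 required"
            )


class AncestralMap:
    """Lookup (chrom, pos) -> ancestral allele, for polarizing ALT dosages.

    Built from a tab-separated file (``chrom  pos  ancestral_allele``, ``#``
    comments allowed) or from the ``AA`` INFO tag of a VCF.
    """

    def __init__(self, mapping: dict[tuple[str, int], str]):
        for (chrom, pos), allele in mapping.items():
            if len(allele) != 1:
                raise ValueError(
                    f"ancestral allele at {chrom}:{pos} is '{allele}'; single nucleotides only"
                )
        self.mapping = {k: v.upper() for k, v in mapping.items()}

    def get(self, chrom: str, pos: int) -> str | None:
        return self.mapping.get((str(chrom), int(pos)))

    def __len__(self) -> int:
        return len(self.mapping)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AncestralMap":
        mapping: dict[tuple[str, int], str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos, allele = line.split("\t")[:3]
                mapping[(chrom, int(pos))] = allele
        return cls(mapping)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "AncestralMap":
        """Collect per-site ``AA`` INFO tags from a VCF."""
        from cyvcf2 import VCF

        mapping: dict[tuple[str, int], str] = {}
        for variant in VCF(str(path)):
            aa = variant.INFO.get("AA")
            if aa and len(aa) == 1 and aa.upper() in "ACGT":
                mapping[(variant.CHROM, variant.POS)] = aa.upper()
        return cls(mapping)
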