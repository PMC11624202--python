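"""VCF ingestion: site filters, HWE exact test, polarization, locus sets.

The quality-control pipeline mirrors common short-read population-genomics
practice: keep only biallelic SNPs with complete genotypes, drop sites with
low site quality (QUAL), low mapping quality (MQ), any sample below a minimum
depth or a site mean depth far above the dataset average, and drop sites that
depart from Hardy-Weinberg equilibrium under an exact conditional test.
Dosages are read on the ALT allele; :func:`polarize_to_derived` flips them to
derived-allele counts using an ancestral-allele map.
"""

from __future__ import annotations

import logging
from math import lgamma
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    CATEGORY_SEVERITY,
    LOF_CONSEQUENCES,
    AncestralMap,
    GenotypeMatrix,
    InsufficientLociError,
    LocusSet,
)

__all__ = [
    "read_vcf_genotypes",
    "hwe_exact_test",
    "polarize_to_derived",
    "select_locus_set",
    "annotations_from_tsv",
    "annotations_from_vcf_csq",
    "apply_annotations",
]

logger = logging.getLogger("genld.vcfio")


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test conditional on allele counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts; the p-value sums the probabilities of all configurations no more
    likely than the observed one (ties included). Monomorphic samples admit a
    single configuration and return 1.0.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_alt = n_het + 2 * n_hom_alt
    two_n = 2 * n
    if n_alt == 0 or n_alt == two_n:
        return 1.0
    # P(het = b | n, n_alt) ∝ n! / (a! b! c!) * 2^b  with a = (n_alt - b)/2
    b_max = min(n_alt, two_n - n_alt)
    bs = np.arange(n_alt % 2, b_max + 1, 2)
    a = (n_alt - bs) // 2
    c = n - a - bs
    log_w = (
        bs * np.log(2.0)
        - _lgamma_arr(a + 1)
        - _lgamma_arr(bs + 1)
        - _lgamma_arr(c + 1)
    )
    probs = np.exp(log_w - log_w.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(bs == n_het)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    return np.vectorize(lgamma)(x)


def read_vcf_genotypes(
    path: str | Path,
    min_qual: float = 20.0,
    min_mq: float = 40.0,
    min_dp: float = 3.0,
    max_dp_frac: float = 2.5,
    hwe_alpha: float | None = 1e-6,
) -> GenotypeMatrix:
    """Read a VCF into an ALT-dosage :class:`GenotypeMatrix` with QC filters.

    Filters, in order: biallelic SNPs only; no missing genotypes; QUAL >=
    ``min_qual`` and INFO/MQ >= ``min_mq`` (sites without the field pass);
    every sample's FORMAT/DP >= ``min_dp`` and site mean depth <=
    ``max_dp_frac`` x the dataset-wide mean depth (skipped when DP is absent);
    HWE exact p >= ``hwe_alpha`` (``None`` disables). Dosages count ALT
    alleles; polarize afterwards. Filter counts are logged.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise ValueError(f"cannot parse VCF '{path}': {exc}") from exc
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    if n == 0:
        raise ValueError(f"VCF '{path}' has no sample columns")

    counts = {
        "total": 0,
        "not_biallelic_snp": 0,
        "missing_genotype": 0,
        "low_qual": 0,
        "low_mq": 0,
        "low_dp": 0,
        "high_dp": 0,
        "hwe_fail": 0,
        "kept": 0,
    }
    rows = []  # (chrom, pos, ref, alt, dosage vector, mean_dp or nan)
    for variant in vcf:
        counts["total"] += 1
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            counts["not_biallelic_snp"] += 1
            continue
        gts = variant.genotype.array()[:, :2]
        if (gts < 0).any():
            counts["missing_genotype"] += 1
            continue
        if variant.QUAL is not None and variant.QUAL < min_qual:
            counts["low_qual"] += 1
            continue
        mq = variant.INFO.get("MQ")
        if mq is not None and mq < min_mq:
            counts["low_mq"] += 1
            continue
        try:
            dp = variant.format("DP")
        except KeyError:  # header defines no FORMAT/DP: depth filters skipped
            dp = None
        mean_dp = np.nan
        if dp is not None:
            dp = dp.astype(float).ravel()[:n]
            if np.nanmin(dp) < min_dp:
                counts["low_dp"] += 1
                continue
            mean_dp = float(np.nanmean(dp))
        dosage = gts.sum(axis=1).astype(np.int8)
        if hwe_alpha is not None:
            n_het = int(((gts[:, 0] != gts[:, 1])).sum())
            n_hom_alt = int(((gts[:, 0] == 1) & (gts[:, 1] == 1)).sum())
            if hwe_exact_test(n - n_het - n_hom_alt, n_het, n_hom_alt) < hwe_alpha:
                counts["hwe_fail"] += 1
                continue
        rows.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0], dosage, mean_dp))

    # dataset-wide mean depth over the sites that reached the depth stage
    depths = np.array([r[5] for r in rows], dtype=float)
    if np.isfinite(depths).any():
        cutoff = max_dp_frac * np.nanmean(depths)
        kept_rows = []
        for row in rows:
            if np.isfinite(row[5]) and row[5] > cutoff:
                counts["high_dp"] += 1
            else:
                kept_rows.append(row)
        rows = kept_rows

    counts["kept"] = len(rows)
    logger.info("VCF '%s' filter counts: %s", path, counts)
    if not rows:
        raise InsufficientLociError(
            f"insufficient loci: no sites in '{path}' survived filtering: {counts}"
        )
    loci = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "ref": [r[2] for r in rows],
            "alt": [r[3] for r in rows],
        }
    )
    dosages = np.column_stack([r[4] for r in rows])
    return GenotypeMatrix(dosages=dosages, loci=loci, sample_ids=sample_ids)


def polarize_to_derived(gm: GenotypeMatrix, aa: AncestralMap) -> GenotypeMatrix:
    """Convert ALT dosages to derived-allele dosages using an ancestral map.

    Per locus: ancestral == REF leaves the dosage unchanged (ALT is derived);
    ancestral == ALT flips dosage to ``2 - dosage``; an ancestral allele
    matching neither, or missing, drops the locus. Loci monomorphic after
    polarization are dropped too. Drop counts are logged.
    """
    if "ref" not in gm.loci.columns or "alt" not in gm.loci.columns:
        raise ValueError("genotype matrix lacks ref/alt metadata; cannot polarize")
    keep, flip = [], []
    n_unresolved = 0
    for j, row in gm.loci.iterrows():
        anc = aa.get(row["chrom"], int(row["pos"]))
        if anc == str(row["ref"]).upper():
            keep.append(j)
            flip.append(False)
        elif anc == str(row["alt"]).upper():
            keep.append(j)
            flip.append(True)
        else:
            n_unresolved += 1
    dosages = gm.dosages[:, keep].copy()
    flip = np.asarray(flip, dtype=bool)
    dosages[:, flip] = 2 - dosages[:, flip]
    loci = gm.loci.iloc[keep].reset_index(drop=True).copy()
    loci["ancestral_is_alt"] = flip
    loci["dac"] = dosages.sum(axis=0).astype(int)
    out = GenotypeMatrix(dosages=dosages, loci=loci, sample_ids=list(gm.sample_ids))
    polymorphic = out.drop_monomorphic()
    logger.info(
        "polarized %d loci: %d unresolved ancestral dropped, %d flipped, "
        "%d monomorphic after polarization dropped",
        gm.n_loci,
        n_unresolved,
        int(flip.sum()),
        out.n_loci - polymorphic.n_loci,
    )
    return polymorphic


def select_locus_set(
    gm: GenotypeMatrix,
    category: str = "custom",
    mdac: int | None = None,
    mdaf: float | None = None,
    min_dac: int = 2,
    indices: np.ndarray | None = None,
) -> LocusSet:
    """Build a frequency-conditioned locus set from one functional category.

    Members must carry the category label (or fall in explicit ``indices``
    when category is "custom"), have dac >= ``min_dac`` (default 2: doubletons
    and up, robust to singleton calling error) and satisfy the mdac / mdaf
    ceilings when set. Indices come back sorted by (chrom, pos).
    """
    if min_dac < 1:
        raise ValueError("min_dac must be >= 1")
    if category == "custom":
        if indices is None:
            raise ValueError("category 'custom' requires explicit indices")
        cand = np.asarray(indices, dtype=int)
    else:
        if "category" not in gm.loci.columns:
            raise ValueError("genotype matrix has no 'category' annotation column")
        cand = np.flatnonzero((gm.loci["category"] == category).to_numpy())
    dac = gm.dac[cand]
    ok = dac >= min_dac
    if mdac is not None:
        ok &= dac <= mdac
    if mdaf is not None:
        ok &= dac / (2 * gm.n_individuals) <= mdaf
    cand = cand[ok]
    order = np.lexsort(
        (gm.loci["pos"].to_numpy()[cand], gm.loci["chrom"].to_numpy().astype(str)[cand])
    )
    cand = cand[order]
    if len(cand) < 2:
        raise InsufficientLociError(
            f"insufficient loci: category '{category}' with min_dac={min_dac}, "
            f"mdac={mdac}, mdaf={mdaf} leaves {len(cand)} loci (>= 2 required)"
        )
    return LocusSet(source=gm, indices=cand, label=category, mdac=mdac, mdaf=mdaf)


# -- functional annotations ---------------------------------------------------


def annotations_from_tsv(path: str | Path) -> dict[tuple[str, int], str]:
    """Read (chrom, pos, category) rows; '#' comments allowed."""
    mapping: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, pos, category = line.split("\t")[:3]
            mapping[(chrom, int(pos))] = category
    return mapping


def _csq_category(consequences: list[str]) -> str | None:
    best: str | None = None
    for term in consequences:
        if term in LOF_CONSEQUENCES:
            cat = "LoF"
        elif term == "missense_variant":
            cat = "missense"
        elif term == "synonymous_variant":
            cat = "synonymous"
        else:
            continue
        if best is None or CATEGORY_SEVERITY[cat] > CATEGORY_SEVERITY[best]:
            best = cat
    return best


def annotations_from_vcf_csq(path: str | Path) -> dict[tuple[str, int], str]:
    """Collect categories from a VEP-style ``CSQ`` INFO field.

    The first ``&``-separated consequence term of each transcript entry is
    considered; across transcripts the most severe category wins
    (LoF > missense > synonymous). Sites with no recognized term are omitted.
    """
    from cyvcf2 import VCF

    mapping: dict[tuple[str, int], str] = {}
    for variant in VCF(str(path)):
        csq = variant.INFO.get("CSQ")
        if not csq:
            continue
        terms = [entry.split("|")[0].split("&")[0] for entry in csq.split(",")]
        cat = _csq_category(terms)
        if cat is not None:
            mapping[(variant.CHROM, variant.POS)] = cat
    return mapping


def apply_annotations(
    gm: GenotypeMatrix, mapping: dict[tuple[str, int], str], default: str = "unannotated"
) -> GenotypeMatrix:
    """Attach a ``category`` column looked up by (chrom, pos)."""
    cats = [
        mapping.get((str(row["chrom"]), int(row["pos"])), default)
        for _, row in gm.loci.iterrows()
    ]
    loci = gm.loci.copy()
    loci["category"] = cats
    return GenotypeMatrix(dosages=gm.dosages, loci=loci, sample_ids=list(gm.sample_ids))
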