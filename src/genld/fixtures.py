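"""Deterministic synthetic genotype data with controllable LD structure.

The generator builds 2n latent haplotypes from a shared Gaussian template:
locus j assigns its derived alleles to the haplotypes with the top-``dac_j``
scores of ``sqrt(a) * u + sqrt(1-a) * e_j``, where ``u`` is the template and
``e_j`` locus-specific noise. The latent loading ``a`` is calibrated through
the bivariate-normal quadrant probability so the expected pairwise dosage
correlation matches a requested rho, and the top-k rule enforces the derived
allele count spectrum exactly. Haplotypes are then paired at random into
diploid genotypes.

Also ships tiny hand-written VCF / ancestral / annotation fixtures that
exercise every ingestion filter branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix import GenotypeMatrix

__all__ = ["SynthSpec", "synth_genotype_matrix", "write_genotype_vcf", "write_demo_inputs"]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic genotype matrix.

    ``dac_spectrum`` lists the derived allele count of every locus (length =
    number of loci); ``target_pair_correlation`` is the expected dosage
    correlation of every locus pair. Negative values are only feasible for
    two loci (mean pairwise correlation of m loci is bounded below by
    -1/(m-1), and the shared-template construction needs a nonnegative
    loading beyond pairs).
    """

    n_individuals: int
    dac_spectrum: tuple[int, ...]
    target_pair_correlation: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        two_n = 2 * self.n_individuals
        if any(not 1 <= d <= two_n - 1 for d in self.dac_spectrum):
            raise ValueError("every dac must be in [1, 2n-1]")
        if not -1 < self.target_pair_correlation < 1:
            raise ValueError("target_pair_correlation must be in (-1, 1)")
        if self.target_pair_correlation < 0 and len(self.dac_spectrum) > 2:
            raise ValueError(
                "negative pairwise correlation is infeasible for more than two loci"
            )


def _indicator_correlation(a: float, q1: float, q2: float) -> float:
    """Correlation of two top-q threshold indicators of a-correlated normals."""
    z1, z2 = stats.norm.ppf(1 - q1), stats.norm.ppf(1 - q2)
    both = stats.multivariate_normal(cov=[[1.0, a], [a, 1.0]], allow_singular=True).cdf(
        [-z1, -z2]
    )
    return (both - q1 * q2) / np.sqrt(q1 * (1 - q1) * q2 * (1 - q2))


def _calibrate_loading(rho: float, qs: np.ndarray) -> float:
    """Latent loading whose mean pairwise indicator correlation equals rho."""
    if rho == 0.0:
        return 0.0
    pairs = [(qs[i], qs[j]) for i in range(len(qs)) for j in range(i + 1, len(qs))]

    def mean_cor(a: float) -> float:
        return float(np.mean([_indicator_correlation(a, q1, q2) for q1, q2 in pairs]))

    hi = 0.9999
    reach = mean_cor(hi if rho > 0 else -hi)
    if (rho > 0 and reach < rho) or (rho < 0 and reach > rho):
        raise ValueError(
            f"target correlation {rho} infeasible for this dac spectrum "
            f"(attainable extreme ~ {reach:.3f})"
        )
    lo, up = (0.0, hi) if rho > 0 else (-hi, 0.0)
    return float(optimize.brentq(lambda a: mean_cor(a) - rho, lo, up, xtol=1e-6))


def synth_genotype_matrix(spec: SynthSpec) -> GenotypeMatrix:
    """Generate a seeded genotype matrix with the requested LD and spectrum."""
    rng = np.random.default_rng(spec.seed)
    two_n = 2 * spec.n_individuals
    m = len(spec.dac_spectrum)
    qs = np.asarray(spec.dac_spectrum) / two_n
    a = _calibrate_loading(spec.target_pair_correlation, qs)
    u = rng.standard_normal(two_n)
    H = np.zeros((two_n, m), dtype=np.uint8)
    for j, d in enumerate(spec.dac_spectrum):
        if m == 2 and j == 1 and a < 0:
            scores = np.sqrt(-a) * (-u) + np.sqrt(1 + a) * rng.standard_normal(two_n)
        else:
            aa = abs(a) if (m == 2 and a < 0) else a
            scores = np.sqrt(aa) * u + np.sqrt(1 - aa) * rng.standard_normal(two_n)
        H[np.argpartition(scores, -d)[-d:], j] = 1
    # random pairing of haplotypes into individuals
    perm = rng.permutation(two_n)
    dosages = (H[perm[0::2]] + H[perm[1::2]]).astype(np.int8)
    loci = pd.DataFrame(
        {
            "chrom": "synth1",
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "T",
            "category": "custom",
        }
    )
    return GenotypeMatrix(dosages=dosages, loci=loci)


def write_genotype_vcf(gm: GenotypeMatrix, path: str | Path, qual: float = 60.0) -> None:
    """Write a matrix as a minimal VCF 4.2 that round-trips through ingestion.

    Dosages are emitted on the ALT allele; positions must be unique integers
    per chromosome. An ``MQ`` INFO tag is included so quality filters pass.
    """
    loci = gm.loci
    ref = loci["ref"] if "ref" in loci.columns else pd.Series(["A"] * gm.n_loci)
    alt = loci["alt"] if "alt" in loci.columns else pd.Series(["T"] * gm.n_loci)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        code = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(gm.n_loci):
            gts = "\t".join(code[int(x)] for x in gm.dosages[:, j])
            fh.write(
                f"{loci['chrom'].iloc[j]}\t{int(loci['pos'].iloc[j])}\t.\t"
                f"{ref.iloc[j]}\t{alt.iloc[j]}\t{qual:.0f}\t.\tMQ=60\tGT\t{gts}\n"
            )


# -- tiny hand-written ingestion fixtures -------------------------------------

#: two samples; exercises missing-genotype, triallelic, low-QUAL, low-MQ and
#: low-DP branches plus an AA==ALT polarization flip downstream
DEMO_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t60\t.\tMQ=60\tGT:DP\t0/1:20\t1/1:22
chr1\t200\t.\tC\tG\t60\t.\tMQ=60\tGT:DP\t./.:20\t0/1:21
chr1\t300\t.\tG\tA\t60\t.\tMQ=60\tGT:DP\t0/0:19\t0/1:23
chr1\t400\t.\tT\tA,C\t60\t.\tMQ=60\tGT:DP\t0/1:20\t0/2:20
chr1\t500\t.\tA\tC\t10\t.\tMQ=60\tGT:DP\t0/1:20\t0/1:20
chr1\t600\t.\tC\tT\t60\t.\tMQ=20\tGT:DP\t0/1:20\t0/1:20
chr1\t700\t.\tG\tC\t60\t.\tMQ=60\tGT:DP\t0/1:2\t0/1:20
chr1\t800\t.\tA\tG\t60\t.\tMQ=60\tGT:DP\t1/1:21\t0/1:20
"""

#: ancestral alleles: REF at 100 (keep), ALT at 300 and 800 (flip), N at 700,
#: absent for 200 — sites not in the map drop at polarization time
DEMO_ANCESTRAL_TSV = """\
# chrom\tpos\tancestral_allele
chr1\t100\tA
chr1\t300\tA
chr1\t500\tA
chr1\t600\tC
chr1\t700\tN
chr1\t800\tG
"""

DEMO_ANNOTATION_TSV = """\
# chrom\tpos\tcategory
chr1\t100\tsynonymous
chr1\t300\tmissense
chr1\t800\tLoF
"""


def write_demo_inputs(directory: str | Path) -> dict[str, Path]:
    """Write the hand-written demo VCF + TSV fixtures into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {
        "vcf": directory / "demo.vcf",
        "ancestral": directory / "demo_ancestral.tsv",
        "annotations": directory / "demo_annotations.tsv",
    }
    out["vcf"].write_text(DEMO_VCF)
    out["ancestral"].write_text(DEMO_ANCESTRAL_TSV)
    out["annotations"].write_text(DEMO_ANNOTATION_TSV)
    return out
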