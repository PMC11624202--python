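"""Ingestion tests: QC filters, HWE exact test, polarization, locus sets."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from genld.matrix import AncestralMap, GenotypeMatrix, InsufficientLociError
from genld.vcfio import (
    annotations_from_tsv,
    annotations_from_vcf_csq,
    apply_annotations,
    hwe_exact_test,
    polarize_to_derived,
    read_vcf_genotypes,
    select_locus_set,
)

from conftest import random_genotype_matrix


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Brute force: enumerate every genotype-count triple with the observed
    allele counts; P(triple) ∝ multinomial(n; a,b,c) * 2^b."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    configs = []
    for b in range(n + 1):
        for c in range(n - b + 1):
            a = n - b - c
            if b + 2 * c == n_alt:
                weight = comb(n, b) * comb(n - b, c) * 2**b
                configs.append((b, weight))
    total = sum(w for _, w in configs)
    p_obs = next(w for b, w in configs if b == n_het) / total
    return sum(w for _, w in configs if w / total <= p_obs * (1 + 1e-12)) / total


class TestHweExactTest:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (50, 0, 50), (10, 1, 10), (3, 4, 5), (0, 7, 0), (12, 2, 1)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_all_totals_up_to_fifty(self):
        rng = np.random.default_rng(0)
        for n in range(1, 51, 7):
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = n - a - b
            assert hwe_exact_test(a, b, c) == pytest.approx(
                hwe_enumeration_oracle(a, b, c), abs=1e-12
            )

    def test_extreme_departure_is_tiny(self):
        # 50/0/50: all-homozygote split is astronomically unlikely under HWE
        assert hwe_exact_test(50, 0, 50) < 1e-6

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestReadVcf:
    def test_demo_filter_branches(self, demo_inputs):
        gm = read_vcf_genotypes(demo_inputs["vcf"])
        # of 8 sites: missing GT, triallelic, low QUAL, low MQ, low DP drop
        assert list(gm.loci["pos"]) == [100, 300, 800]
        assert gm.sample_ids == ["s1", "s2"]
        np.testing.assert_array_equal(gm.dosages, [[1, 0, 2], [2, 1, 1]])

    def test_qual_threshold_configurable(self, demo_inputs):
        gm = read_vcf_genotypes(demo_inputs["vcf"], min_qual=5.0)
        assert 500 in list(gm.loci["pos"])

    def test_hwe_filter_excludes_departing_site(self, tmp_path):
        from genld.fixtures import write_genotype_vcf

        n = 60
        # site 0: all-homozygote split (HWE p << 1e-6); site 1, 2: balanced
        dosages = np.column_stack(
            [
                np.array([0] * 30 + [2] * 30, dtype=np.int8),
                np.array(([0, 1, 1, 2] * 15), dtype=np.int8),
                np.array(([1, 0, 2, 1] * 15), dtype=np.int8),
            ]
        )
        gm = GenotypeMatrix(
            dosages,
            pd.DataFrame({"chrom": "c1", "pos": [100, 200, 300], "ref": "A", "alt": "T"}),
        )
        path = tmp_path / "hwe.vcf"
        write_genotype_vcf(gm, path)
        kept = read_vcf_genotypes(path)
        assert list(kept.loci["pos"]) == [200, 300]
        no_filter = read_vcf_genotypes(path, hwe_alpha=None)
        assert no_filter.n_loci == 3

    def test_empty_result_raises(self, demo_inputs):
        with pytest.raises(InsufficientLociError, match="survived"):
            read_vcf_genotypes(demo_inputs["vcf"], min_qual=1e9)

    def test_malformed_vcf_raises(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a vcf\n")
        with pytest.raises(ValueError, match="parse"):
            read_vcf_genotypes(bad)


class TestPolarization:
    def test_demo_polarization(self, demo_inputs):
        gm = read_vcf_genotypes(demo_inputs["vcf"])
        aa = AncestralMap.from_tsv(demo_inputs["ancestral"])
        out = polarize_to_derived(gm, aa)
        # pos 100 ancestral==REF: unchanged; 300 and 800 ancestral==ALT: flipped
        assert list(out.loci["pos"]) == [100, 300, 800]
        np.testing.assert_array_equal(out.dosages, [[1, 2, 0], [2, 1, 1]])

    def test_unresolved_ancestral_dropped(self):
        gm = GenotypeMatrix(
            np.array([[0, 0], [1, 1], [2, 2]], dtype=np.int8),
            pd.DataFrame(
                {"chrom": "c", "pos": [10, 20], "ref": ["A", "C"], "alt": ["T", "G"]}
            ),
        )
        aa = AncestralMap({("c", 10): "A", ("c", 20): "N"})
        out = polarize_to_derived(gm, aa)
        assert list(out.loci["pos"]) == [10]

    def test_flip_is_involution(self, rng):
        gm = random_genotype_matrix(rng, n=20, m=10)
        flip_all = AncestralMap(
            {("chr1", int(p)): "T" for p in gm.loci["pos"]}  # ancestral == ALT
        )
        once = polarize_to_derived(gm, flip_all)
        twice = polarize_to_derived(once, flip_all)
        np.testing.assert_array_equal(twice.dosages, gm.dosages)
        np.testing.assert_array_equal(twice.dac, gm.dac)

    def test_monomorphic_after_flip_dropped(self):
        gm = GenotypeMatrix(
            np.array([[2], [2]], dtype=np.int8),
            pd.DataFrame({"chrom": "c", "pos": [10], "ref": ["A"], "alt": ["T"]}),
        )
        out = polarize_to_derived(gm, AncestralMap({("c", 10): "T"}))
        assert out.n_loci == 0


class TestSelectLocusSet:
    def _annotated(self):
        rng = np.random.default_rng(5)
        gm = random_genotype_matrix(rng, n=30, m=12)
        gm.loci["category"] = ["synonymous"] * 6 + ["missense"] * 3 + ["LoF"] * 3
        return gm

    def test_mdac_bounds(self):
        gm = GenotypeMatrix(
            np.array(
                [[1, 1, 1, 2], [0, 1, 2, 2], [0, 0, 0, 2], [0, 0, 0, 2]], dtype=np.int8
            ),
            pd.DataFrame({"chrom": "c", "pos": [1, 2, 3, 4]}),
        )
        ls = select_locus_set(gm, "custom", indices=np.arange(4), mdac=3, min_dac=2)
        assert list(gm.dac[ls.indices]) == [2, 3]

    def test_category_and_mdaf(self):
        gm = self._annotated()
        ls = select_locus_set(gm, "synonymous", mdaf=0.5)
        assert all(gm.loci["category"].iloc[ls.indices] == "synonymous")
        assert (ls.dac / (2 * gm.n_individuals) <= 0.5).all()
        assert (ls.dac >= 2).all()

    def test_insufficient_loci_error(self):
        gm = self._annotated()
        with pytest.raises(InsufficientLociError, match="insufficient loci"):
            select_locus_set(gm, "LoF", mdac=0)

    def test_indices_sorted_by_position(self):
        gm = self._annotated()
        ls = select_locus_set(gm, "synonymous")
        pos = gm.loci["pos"].to_numpy()[ls.indices]
        assert (np.diff(pos) > 0).all()


class TestAnnotations:
    def test_tsv_and_apply(self, demo_inputs):
        ann = annotations_from_tsv(demo_inputs["annotations"])
        assert ann[("chr1", 800)] == "LoF"
        gm = read_vcf_genotypes(demo_inputs["vcf"])
        out = apply_annotations(gm, ann)
        assert list(out.loci["category"]) == ["synonymous", "missense", "LoF"]

    def test_csq_most_severe_wins(self, tmp_path):
        vcf = tmp_path / "csq.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "##contig=<ID=c1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "c1\t10\t.\tA\tT\t60\t.\tCSQ=synonymous_variant|x,stop_gained|y\tGT\t0/1\n"
            "c1\t20\t.\tA\tT\t60\t.\tCSQ=missense_variant&splice_region_variant|x\tGT\t0/1\n"
            "c1\t30\t.\tA\tT\t60\t.\tCSQ=intron_variant|x\tGT\t0/1\n"
        )
        ann = annotations_from_vcf_csq(vcf)
        assert ann[("c1", 10)] == "LoF"
        assert ann[("c1", 20)] == "missense"
        assert ("c1", 30) not in ann


def test_column_sums_equal_dac_after_pipeline(demo_inputs):
    gm = read_vcf_genotypes(demo_inputs["vcf"])
    out = polarize_to_derived(gm, AncestralMap.from_tsv(demo_inputs["ancestral"]))
    np.testing.assert_array_equal(out.dac, out.dosages.sum(axis=0))
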