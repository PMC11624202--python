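"""Unit and property tests for the set-level LD statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genld.ldstats import (
    HaplotypeCounts,
    PairFilter,
    ZeroVarianceError,
    classical_two_locus,
    dosage_correlation,
    ldcor,
    ldcorabs,
    netld,
    nldcor,
    nldcorabs,
    signed_sqrt_r2_mean,
    v_over_va,
)
from genld.matrix import GenotypeMatrix, LocusSet

from conftest import as_locus_set, random_genotype_matrix


def _matrix(columns) -> LocusSet:
    dosages = np.column_stack([np.asarray(c, dtype=np.int8) for c in columns])
    m = dosages.shape[1]
    gm = GenotypeMatrix(
        dosages, pd.DataFrame({"chrom": "c", "pos": np.arange(1, m + 1) * 100})
    )
    return as_locus_set(gm)


def brute_force_pair_mean(X: np.ndarray, absolute: bool = False, raw: bool = False) -> float:
    """O(m^2) reference: explicit double loop over pairs."""
    m = X.shape[1]
    vals = []
    for i in range(m):
        for j in range(i + 1, m):
            if raw:
                v = float(np.cov(X[:, i], X[:, j], ddof=1)[0, 1])
            else:
                v = dosage_correlation(X[:, i], X[:, j])
            vals.append(abs(v) if absolute else v)
    return float(np.mean(vals))


class TestDosageCorrelation:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((2, 0, 0, 0), (2, 0, 0, 0), 1.0),
            ((2, 0), (0, 2), -1.0),
            ((1, 1, 0, 0), (1, 0, 1, 0), 0.0),
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert dosage_correlation(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ZeroVarianceError):
            dosage_correlation(np.array([1, 1, 1]), np.array([0, 1, 2]))


class TestSetStatistics:
    def test_ldcor_identical_columns(self):
        assert ldcor(_matrix([(2, 0, 0, 0), (2, 0, 0, 0)])).value == pytest.approx(1.0)

    def test_ldcor_three_repulsion_singletons(self):
        # three mutually exclusive carriers: each pair correlates at -1/3
        ls = _matrix([(2, 0, 0, 0), (0, 2, 0, 0), (0, 0, 2, 0)])
        assert ldcor(ls).value == pytest.approx(-1 / 3)

    def test_ldcorabs_orthogonal_columns_zero(self):
        ls = _matrix([(1, 1, 0, 0), (1, 0, 1, 0), (1, 0, 0, 1)])
        assert ldcorabs(ls).value == pytest.approx(0.0, abs=1e-14)

    def test_netld_identical_columns_is_variance(self):
        assert netld(_matrix([(2, 0, 0, 0), (2, 0, 0, 0)])).value == pytest.approx(1.0)

    def test_netld_zero_covariance_pair(self):
        assert netld(_matrix([(1, 1, 0, 0), (1, 0, 1, 0)])).value == pytest.approx(0.0)

    def test_v_over_va_identical_columns(self):
        ls = _matrix([(2, 0, 0, 0), (2, 0, 0, 0)])
        out = v_over_va(ls)
        assert out["compact_form"] == pytest.approx(1.5)
        assert out["direct_ratio"] == pytest.approx(2.0)

    def test_v_over_va_is_one_when_netld_zero(self):
        ls = _matrix([(1, 1, 0, 0), (1, 0, 1, 0)])
        assert v_over_va(ls)["compact_form"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_fast_path_matches_pair_loop(self, seed):
        rng = np.random.default_rng(seed)
        gm = random_genotype_matrix(rng, n=20, m=50)
        ls = as_locus_set(gm)
        X = gm.dosages.astype(float)
        assert ldcor(ls).value == pytest.approx(brute_force_pair_mean(X), abs=1e-10)
        assert netld(ls).value == pytest.approx(
            brute_force_pair_mean(X, raw=True), abs=1e-10
        )
        assert ldcorabs(ls).value == pytest.approx(
            brute_force_pair_mean(X, absolute=True), abs=1e-10
        )

    def test_bounds_and_ordering(self, rng):
        for _ in range(20):
            gm = random_genotype_matrix(rng, n=15, m=8)
            ls = as_locus_set(gm)
            lo = ldcor(ls).value
            hi = ldcorabs(ls).value
            assert -1.0 - 1e-12 <= lo <= hi <= 1.0 + 1e-12
            assert hi >= -1e-12

    def test_individual_permutation_invariance(self, rng):
        gm = random_genotype_matrix(rng, n=30, m=10)
        perm = rng.permutation(gm.n_individuals)
        gm2 = GenotypeMatrix(gm.dosages[perm], gm.loci.copy())
        assert ldcor(as_locus_set(gm)).value == pytest.approx(
            ldcor(as_locus_set(gm2)).value, abs=1e-12
        )

    def test_subsampled_ldcorabs_close_to_exact(self, rng):
        gm = random_genotype_matrix(rng, n=40, m=60)
        ls = as_locus_set(gm)
        exact = ldcorabs(ls, max_pairs=None)
        sub = ldcorabs(ls, max_pairs=800, seed=0)
        assert sub.computation_path == "subsampled"
        assert sub.n_pairs == 800
        assert sub.value == pytest.approx(exact.value, abs=0.05)

    def test_too_few_loci_rejected(self):
        gm = random_genotype_matrix(np.random.default_rng(0), n=10, m=3)
        ls = LocusSet(source=gm, indices=np.array([1]))
        with pytest.raises(Exception, match="2"):
            ldcor(ls)


class TestPairFilter:
    def test_distance_mask_counts(self):
        # positions 100..500 step 100: min 250 bp keeps pairs >= 3 steps apart
        gm = random_genotype_matrix(np.random.default_rng(3), n=30, m=5)
        ls = as_locus_set(gm)
        gm.loci["pos"] = [100, 200, 300, 400, 500]
        res = ldcor(ls, PairFilter(min_distance_bp=250))
        assert res.n_pairs == 3  # (1,4),(1,5),(2,5)
        assert res.computation_path == "exact"

    def test_cross_chromosome_infinite_distance(self):
        gm = random_genotype_matrix(np.random.default_rng(4), n=30, m=4)
        gm.loci["chrom"] = ["c1", "c1", "c2", "c2"]
        ls = as_locus_set(gm)
        admitted = ldcor(ls, PairFilter(min_distance_bp=1e9)).n_pairs
        assert admitted == 4  # only the 4 cross-chromosome pairs survive
        capped = ldcor(ls, PairFilter(max_distance_bp=1e9)).n_pairs
        assert capped == 2  # only the 2 within-chromosome pairs survive
        same = ldcor(ls, PairFilter(same_chrom_only=True)).n_pairs
        assert same == 2

    def test_filtered_path_matches_manual_restriction(self, rng):
        gm = random_genotype_matrix(rng, n=25, m=12)
        ls = as_locus_set(gm)
        pf = PairFilter(min_distance_bp=35)
        res = ldcor(ls, pf)
        mask = pf.pair_mask(gm.loci["chrom"].to_numpy(), gm.loci["pos"].to_numpy())
        vals = [
            dosage_correlation(gm.dosages[:, i], gm.dosages[:, j])
            for i, j in zip(*np.nonzero(mask))
        ]
        assert res.value == pytest.approx(float(np.mean(vals)), abs=1e-12)


class TestNormalizedDifference:
    def test_self_difference_zero(self):
        ls = _matrix([(2, 0, 0, 0), (0, 2, 0, 0), (0, 0, 2, 0)])
        r = ldcor(ls)
        assert nldcor(r, r) == 0.0

    def test_subtraction(self):
        target = ldcor(_matrix([(2, 0, 0, 0), (0, 2, 0, 0), (0, 0, 2, 0)]))
        null = ldcor(_matrix([(2, 0, 0, 0), (2, 0, 0, 0)]))
        assert nldcor(target, null) == pytest.approx(-1 / 3 - 1.0)

    def test_mismatched_filters_rejected(self):
        ls = _matrix([(2, 0, 0, 0), (0, 2, 0, 0)])
        a = ldcor(ls, PairFilter())
        b = ldcor(ls, PairFilter(min_distance_bp=50))
        with pytest.raises(ValueError, match="pair filter"):
            nldcor(a, b)
        with pytest.raises(ValueError, match="ldcor"):
            nldcorabs(a, a)


class TestClassicalTwoLocus:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((50, 0, 0, 50), {"D": 0.25, "D_prime": 1.0, "r2": 1.0}),
            ((25, 25, 25, 25), {"D": 0.0, "D_prime": 0.0, "r2": 0.0}),
            ((10, 10, 10, 70), {"D": 0.06, "D_prime": 0.375, "r2": 0.140625}),
        ],
    )
    def test_worked_examples(self, counts, expected):
        out = classical_two_locus(HaplotypeCounts(*counts))
        for key, val in expected.items():
            assert out[key] == pytest.approx(val)

    def test_signed_sqrt_r2_sign_follows_d(self):
        out = classical_two_locus(HaplotypeCounts(5, 20, 20, 55))
        assert out["D"] < 0
        assert out["signed_sqrt_r2"] == pytest.approx(-np.sqrt(out["r2"]))

    def test_monomorphic_rejected(self):
        with pytest.raises(ZeroVarianceError):
            classical_two_locus(HaplotypeCounts(50, 50, 0, 0))


class TestSignedSqrtR2Mean:
    def test_perfect_coupling(self):
        H = np.tile(np.array([[1], [1], [0], [0]]), (1, 3))
        assert signed_sqrt_r2_mean(H) == pytest.approx(1.0)

    def test_perfect_repulsion(self):
        H = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        assert signed_sqrt_r2_mean(H) == pytest.approx(-1.0)

    def test_matches_per_pair_classical_values(self, rng):
        H = (rng.random((40, 6)) < rng.uniform(0.2, 0.8, size=6)).astype(np.uint8)
        H = H[:, (H.sum(axis=0) > 0) & (H.sum(axis=0) < 40)]
        vals = []
        for i in range(H.shape[1]):
            for j in range(i + 1, H.shape[1]):
                n_ab = int((H[:, i] & H[:, j]).sum())
                n_a = int(H[:, i].sum())
                n_b = int(H[:, j].sum())
                h = HaplotypeCounts(
                    n_ab, n_a - n_ab, n_b - n_ab, H.shape[0] - n_a - n_b + n_ab
                )
                vals.append(classical_two_locus(h)["signed_sqrt_r2"])
        assert signed_sqrt_r2_mean(H) == pytest.approx(float(np.mean(vals)), abs=1e-12)

    def test_unphased_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            signed_sqrt_r2_mean(np.array([[2, 0], [0, 2]]))


@settings(derandomize=True, max_examples=40)
@given(
    data=st.data(),
    n=st.integers(min_value=4, max_value=25),
    m=st.integers(min_value=2, max_value=12),
)
def test_property_bounds_hold_on_arbitrary_matrices(data, n, m):
    """-1 <= LDcor <= LDcorabs <= 1 on any polymorphic dosage matrix."""
    seed = data.draw(st.integers(min_value=0, max_value=2**31 - 1))
    gm = random_genotype_matrix(np.random.default_rng(seed), n=n, m=m)
    ls = as_locus_set(gm)
    lo, hi = ldcor(ls).value, ldcorabs(ls).value
    assert -1.0 - 1e-9 <= lo <= hi + 1e-12 <= 1.0 + 1e-9
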