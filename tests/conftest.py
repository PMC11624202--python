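import numpy as np
import pandas as pd
import pytest

from genld.matrix import GenotypeMatrix, LocusSet


def random_genotype_matrix(
    rng: np.random.Generator, n: int, m: int, polymorphic: bool = True
) -> GenotypeMatrix:
    """Dosage matrix with iid columns; polymorphic + non-constant by rejection."""
    cols = []
    while len(cols) < m:
        p = rng.uniform(0.05, 0.95)
        col = rng.binomial(2, p, size=n).astype(np.int8)
        if polymorphic and (col.min() == col.max() or not 0 < col.sum() < 2 * n):
            continue
        cols.append(col)
    dosages = np.column_stack(cols)
    loci = pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, m + 1) * 10, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(dosages=dosages, loci=loci)


def as_locus_set(gm: GenotypeMatrix, label: str = "custom") -> LocusSet:
    return LocusSet(source=gm, indices=np.arange(gm.n_loci), label=label)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def demo_inputs(tmp_path):
    from genld.fixtures import write_demo_inputs

    return write_demo_inputs(tmp_path / "demo")
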