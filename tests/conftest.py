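import numpy as np
import pytest

from prskit import (
    CohortSimConfig,
    DenseGenotypeMatrix,
    GenotypeCall,
    VariantKey,
    matrix_from_calls,
    simulate_cohort,
)


def make_random_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_variants: int,
    missing_rate: float = 0.0,
    n_alts_max: int = 1,
) -> DenseGenotypeMatrix:
    """Random dense matrix over two chromosomes; optionally multi-allelic."""
    bases = "ACGT"
    keys = []
    pos = {"chr1": 100, "chr2": 100}
    for i in range(n_variants):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        pos[chrom] += int(rng.integers(1, 50))
        ref = bases[rng.integers(4)]
        n_alts = int(rng.integers(1, n_alts_max + 1))
        alts = tuple(b for b in bases if b != ref)[:n_alts]
        keys.append(VariantKey(chrom, pos[chrom], ref, alts))
    alleles = np.zeros((n_variants, n_samples, 2), dtype=np.int16)
    for vi, key in enumerate(keys):
        g = rng.integers(0, key.n_alleles, size=(n_samples, 2))
        alleles[vi] = np.sort(g, axis=1)
    if missing_rate > 0:
        mask = rng.random((n_variants, n_samples)) < missing_rate
        alleles[mask] = -1
    return DenseGenotypeMatrix([f"s{i}" for i in range(n_samples)], keys, alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix():
    """2 samples x 3 variants with het, hom-alt, hom-ref and missing calls."""
    return matrix_from_calls(
        ["s1", "s2"],
        [
            (VariantKey("chr1", 100, "A", ("G",)), [GenotypeCall(0, 1), GenotypeCall(1, 1)]),
            (VariantKey("chr1", 101, "C", ("T",)), [GenotypeCall(0, 0), GenotypeCall(-1, -1)]),
            (VariantKey("chr2", 500, "G", ("A", "T")), [GenotypeCall(0, 2), GenotypeCall(0, 0)]),
        ],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """150 samples x 400 variants, 5% missing, both effect orientations."""
    return simulate_cohort(
        CohortSimConfig(
            n_samples=150,
            n_variants=400,
            missing_rate=0.05,
            effect_orientation="random",
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """200 samples x 300 variants, no missing calls, ALT-effect weights."""
    return simulate_cohort(
        CohortSimConfig(n_samples=200, n_variants=300, missing_rate=0.0, seed=5)
    )
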