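import numpy as np
import pytest

from strpopkit import (
    AlleleLabel,
    FrequencyTable,
    GenotypeDataset,
    LocusGenotype,
    genotype,
    reference_panel,
)


@pytest.fixture(scope="session")
def panel():
    """Packaged 20-locus reference table (frequencies, Ho, printed params)."""
    return reference_panel()


@pytest.fixture(scope="session")
def tpox(panel):
    """Single-locus frequency table for TPOX (7 alleles, He ~ 0.615)."""
    return FrequencyTable("tpox", {"TPOX": panel.frequencies.freqs["TPOX"]})


@pytest.fixture
def small_dataset():
    """4 samples x 2 loci, one missing genotype at L2."""
    calls = [
        [genotype(10, 11), genotype(8, 8)],
        [genotype(10, 10), genotype(8, 11)],
        [genotype(11, 12), LocusGenotype.missing()],
        [genotype(12, 12), genotype(11, 11)],
    ]
    return GenotypeDataset(
        ["S1", "S2", "S3", "S4"], ["Han"] * 4, ["L1", "L2"], calls
    )


def random_dataset(rng: np.random.Generator, n=8, loci=("LA", "LB"), k=4,
                   missing_rate=0.1, micro=True) -> GenotypeDataset:
    """Random small dataset with optional microvariant alleles and missingness."""
    tenths = [80, 90, 93, 100, 110, 123, 140, 290][:k] if micro else \
             [10 * (8 + i) for i in range(k)]
    alleles = [AlleleLabel(t) for t in tenths]
    calls = []
    for i in range(n):
        row = []
        for _ in loci:
            if rng.random() < missing_rate:
                row.append(LocusGenotype.missing())
            else:
                a, b = rng.choice(len(alleles), size=2)
                row.append(LocusGenotype(alleles[a], alleles[b]))
        calls.append(row)
    pops = ["P1" if i < n // 2 else "P2" for i in range(n)]
    return GenotypeDataset([f"S{i+1}" for i in range(n)], pops, list(loci), calls)
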