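import numpy as np
import pandas as pd
import pytest

from vineflow.genotypes import GenotypeMatrix


def make_matrix(dosages, pops=None, sample_ids=None, positions=None, chrom="chr1"):
    """Small GenotypeMatrix builder for toy fixtures."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    pops = pops or ["pop1"] * n
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    loci = pd.DataFrame(
        {
            "chrom": [chrom] * m if isinstance(chrom, str) else chrom,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(
        sample_ids=sample_ids, pop_labels=pops, loci=loci, dosages=dosages
    )


@pytest.fixture(scope="session")
def benchmark_report():
    """Full-scale scenario-discrimination benchmark (shared: it is expensive).

    2000 reference simulations per scenario, 500 loci, 30 diploids per
    population, 20 pseudo-observed datasets per scenario, tolerance 1%.
    """
    from vineflow.benchmarks import separated_benchmark

    return separated_benchmark(seed=42)
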