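import numpy as np
import pytest

from karyobias.genome import ChromosomeSpec, GenomeSpec, human_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def toy_genome():
    """Three tiny chromosomes for exact, hand-checkable tests."""
    return GenomeSpec(
        chromosomes=(
            ChromosomeSpec("A", n_bins=10, centromere_bin=4,
                           radial_mean=0.3, lad_fraction_true=0.2),
            ChromosomeSpec("B", n_bins=8, centromere_bin=3,
                           radial_mean=0.6, lad_fraction_true=0.5),
            ChromosomeSpec("C", n_bins=6, centromere_bin=2,
                           radial_mean=0.8, lad_fraction_true=0.8),
        ),
        bin_size=1_000_000,
    )


@pytest.fixture(scope="session")
def demo_genome():
    """Scaled 23-chromosome genome used by simulation tests (~600 bins)."""
    return human_genome(scale=0.2)
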