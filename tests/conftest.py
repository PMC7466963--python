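import numpy as np
import pytest

from divscape import ChromMap, SpikeSpec, balding_nichols, spiked_landscape


@pytest.fixture(scope="session")
def bn_matrix():
    """Moderate two-population Balding–Nichols matrix (F = 0.1)."""
    return balding_nichols(n1=20, n2=20, n_snps=2000, f=0.1, seed=11,
                           spacing_bp=1000, invariant_every=4)


@pytest.fixture(scope="session")
def spiked():
    """Spiked landscape with one island and one valley plus its truth set."""
    spec = SpikeSpec(
        background_f=0.02, island_f=0.5,
        islands=[("chr1", 8_000_000, 9_000_000)],
        valleys=[("chr1", 14_000_000, 15_000_000)],
        chrom_lengths={"chr1": 20_000_000},
        snp_spacing_bp=2500, invariant_every=5, window_bp=50_000,
    )
    gm, truth = spiked_landscape(spec, seed=5)
    return spec, gm, truth


@pytest.fixture(scope="session")
def chrom_map_single():
    return ChromMap(names=["chr1"], length_bp={"chr1": 20_000_000})
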