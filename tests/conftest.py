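import numpy as np
import pytest

from cistromekit.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_study():
    """One shared desk-scale synthetic study (sequence-bearing)."""
    return simulate_study(SimConfig(seed=11))


@pytest.fixture(scope="session")
def tag_scale_config():
    """Sequencing-scale, sequence-free configuration for peak-caller
    recovery: 100 planted sites, background rate 0.5."""
    return SimConfig(
        seed=11, n_chroms=10, chrom_length=10_000_000, with_sequence=False,
        n_genes=0, n_sites=100, shared_site_fraction=0.0,
        frac_regulated_genes=0.0, background_rate=0.5,
        n_chip_tags=20_000, n_input_tags=10_000,
    )


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
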