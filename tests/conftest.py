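import numpy as np
import pytest

from msreprime.design_core import DesignParameters
from msreprime.genome_io import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted-truth genome shared by read-only tests."""
    spec = FixtureSpec(
        n_chroms=1,
        chrom_length=12_000,
        n_cpg_islands=3,
        n_snps=25,
        n_repeats=3,
        n_genes=3,
        planted_enzyme_sites=(("HpaII", 2),),
        seed=11,
    )
    genome, tracks, truth = generate_fixture(spec)
    return spec, genome, tracks, truth


@pytest.fixture()
def relaxed_params():
    """Constraints loose enough that most windows survive."""
    return DesignParameters(
        size_min=18, size_opt=20, size_max=22,
        tm_min=0.0, tm_opt=60.0, tm_max=200.0,
        gc_min=0.0, gc_opt=50.0, gc_max=100.0,
        product_size_ranges=((36, 400),),
        max_self_any=100.0, max_self_end=100.0,
        max_poly_x=50,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
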