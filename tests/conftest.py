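import numpy as np
import pandas as pd
import pytest

from episcope import simulate


@pytest.fixture(scope="session")
def small_config():
    """A reduced world for unit tests: 200 bins, 16 donors, 192 cells."""
    return simulate.SimConfig(
        cohort_design={"exposure": 4, "hiv_pre": 4, "flu_pre": 4, "commercial": 4},
        cells_per_donor_per_celltype=4,
        genome=(("chr1", 500_000), ("chr2", 500_000)),
        n_edmr_true=15,
        n_snps=120,
        n_gdmr_true=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    genotypes = simulate.simulate_genotypes(small_config)
    counts, truth, cell_meta = simulate.simulate_methylomes(small_config, genotypes)
    return {
        "config": small_config,
        "genotypes": genotypes,
        "counts": counts,
        "truth": truth,
        "cell_meta": cell_meta,
    }


@pytest.fixture(scope="session")
def levels_world():
    """Region-level cascade world: 300 regions, 30 planted, 10 samples/cohort."""
    levels, samples, truth = simulate.simulate_region_levels(
        n_regions=300, n_true=30, delta=0.2, level_sd=0.05, seed=11
    )
    return {"levels": levels, "samples": samples, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
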