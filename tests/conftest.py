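import numpy as np
import pytest

from clonalpop import synthetic as syn


@pytest.fixture(scope="session")
def small_sim():
    """One modest clonal population with hybrids, shared across tests."""
    cfg = syn.SimConfig(
        n_haploid_lineages=8,
        genome_length=400_000,
        n_contigs=4,
        n_hybrid_events=4,
        descendants_per_event=(2, 3),
        n_regions=25,
        seed=11,
    )
    strains, truth, gm = syn.simulate_population(cfg)
    return cfg, strains, truth, gm


@pytest.fixture(scope="session")
def small_sim_regions(small_sim):
    cfg, strains, truth, gm = small_sim
    rng = np.random.default_rng(cfg.seed + 1)
    return syn.region_alignments(strains, cfg, rng)
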