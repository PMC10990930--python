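import numpy as np
import pytest

from pirsil.pipeline import process_library
from pirsil.simulate import (PlantedSiteSpec, build_genome, plant_target_sites,
                             simulate_srna_library)
from pirsil.srna import GenomeIndex
from pirsil.workflows import small_config


@pytest.fixture(scope="session")
def params():
    from pirsil.duplex import load_default_params

    return load_default_params()


@pytest.fixture(scope="session")
def bundle():
    """Small genome with two planted 3'UTR binders on the linked locus pair."""
    from pirsil.simulate.genome import valid_gu_position

    b = build_genome(small_config(), seed=7)
    seq2 = b.pirna_truth.set_index("locus_id").loc["tru21ur-0002", "sequence"]
    return plant_target_sites(b, [
        PlantedSiteSpec(pirna_id="tru21ur-0001", utr_offset=30),
        PlantedSiteSpec(pirna_id="tru21ur-0002", utr_offset=150,
                        gu_positions=(valid_gu_position(seq2),)),
    ], seed=7)


@pytest.fixture(scope="session")
def index(bundle):
    return GenomeIndex(bundle.sequences)


def _libs(bundle, index, state, n, depth, seed0):
    out = []
    for r in range(n):
        sim = simulate_srna_library(bundle, state, depth=depth, seed=seed0 + r,
                                    name=f"{state}-{r + 1}")
        out.append(process_library(sim.read_counts, index, bundle.features,
                                   name=sim.name, genome_id=bundle.genome_id,
                                   meta=sim.meta))
    return out


@pytest.fixture(scope="session")
def licensed_libs(bundle, index):
    return _libs(bundle, index, "licensed", 2, 150_000, seed0=41)


@pytest.fixture(scope="session")
def repressed_libs(bundle, index):
    return _libs(bundle, index, "repressed", 2, 150_000, seed0=61)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240207)
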