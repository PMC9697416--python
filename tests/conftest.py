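"""Shared fixtures: one synthetic multi-family population reused across tests."""

import numpy as np
import pytest

from gxemap import genotypes as gt
from gxemap import simulate as sim
from gxemap.popstruct import pca_genotypes
from gxemap.regions import xu_kinship


@pytest.fixture(scope="session")
def gmap():
    # two chromosomes, dense enough for LD structure at desk scale
    return sim.make_genetic_map(2, 150, 80_000_000, cm_per_mb=1.2, seed=11)


@pytest.fixture(scope="session")
def population(gmap):
    """Six DH families (234 lines); ~65% of markers polymorphic per family,
    so families share founder alleles at the remainder (as in real
    multi-family panels)."""
    specs = sim.default_family_specs()
    fams = sim.simulate_families(specs, gmap, seed=12, polymorphic_frac=0.65)
    return sim.merge_families(fams)


@pytest.fixture(scope="session")
def numeric_population(population):
    return gt.encode_numeric(population)


@pytest.fixture(scope="session")
def kinship(numeric_population):
    return xu_kinship(numeric_population.numeric)


@pytest.fixture(scope="session")
def pcs(numeric_population):
    scores, _ = pca_genotypes(numeric_population.numeric, 6)
    return scores


@pytest.fixture(scope="session")
def env_specs():
    return sim.default_env_specs()
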