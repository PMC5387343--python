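import pandas as pd
import pytest

from methnuc import (
    nucleosome_features as nf,
    read_midpoints as rm,
    synthetic_chromatin as sc,
)


@pytest.fixture(scope="session")
def sim():
    """A small seeded synthetic dataset shared across tests."""
    params = sc.SimParams(
        seed=11, genome_length=300_000, segment_length=5_000,
        read_depth=8.0, coverage=8.0,
    )
    return sc.simulate(params)


@pytest.fixture(scope="session")
def sim_midpoints(sim):
    return rm.derive_midpoints(rm.reads_from_bed(sim.nuc_reads), sim.genome)


@pytest.fixture(scope="session")
def sim_records(sim):
    return pd.concat([sim.hcg, sim.gch], ignore_index=True)


@pytest.fixture(scope="session")
def sim_features(sim, sim_midpoints, sim_records):
    return nf.compute_features(sim_midpoints, sim.genome, sim_records)
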