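"""Shared fixtures: the synthetic studies are expensive, so build them once."""

from __future__ import annotations

import pytest

from allele4c.alleleseq import demultiplex_and_map
from allele4c.synthetic_data import (
    ReadSimSpec,
    compartment_scenario,
    default_scenario,
    simulate_reads,
)

SEED = 1


@pytest.fixture(scope="session")
def scen():
    """The compact default study: 10 Mb cis + 6 Mb trans, PE + SE viewpoints."""
    return default_scenario(seed=SEED)


@pytest.fixture(scope="session")
def lym_sim(scen):
    """1e5 error-free PE reads from the lymphoid contact model."""
    return simulate_reads(
        scen.hap,
        scen.models["lymphoid"],
        scen.dbs,
        ReadSimSpec(n_reads=100_000, seed=111),
        scen.viewpoint,
    )


@pytest.fixture(scope="session")
def lym_tables(scen, lym_sim):
    return demultiplex_and_map(lym_sim.pairs(), scen.viewpoint, scen.dbs, sample="lym")


@pytest.fixture(scope="session")
def dom_sim(scen):
    """1e5 error-free PE reads from the decay + domain model (no enrichment)."""
    return simulate_reads(
        scen.hap,
        scen.models["domain_only"],
        scen.dbs,
        ReadSimSpec(n_reads=100_000, seed=211),
        scen.viewpoint,
    )


@pytest.fixture(scope="session")
def dom_tables(scen, dom_sim):
    return demultiplex_and_map(dom_sim.pairs(), scen.viewpoint, scen.dbs, sample="dom")


@pytest.fixture(scope="session")
def comp_scen():
    """The sparse-background study: 6 Mb cis + 78 Mb trans."""
    return compartment_scenario(seed=SEED)


@pytest.fixture(scope="session")
def comp_tables(comp_scen):
    """Capture tables for lymphoid and brain conditions at 1e5 reads each."""
    out = {}
    for condition, seed in (("lymphoid", 21), ("brain", 22)):
        sim = simulate_reads(
            comp_scen.hap,
            comp_scen.models[condition],
            comp_scen.dbs,
            ReadSimSpec(n_reads=100_000, seed=seed),
            comp_scen.viewpoint,
        )
        out[condition] = demultiplex_and_map(
            sim.pairs(), comp_scen.viewpoint, comp_scen.dbs, sample=condition
        )
    return out
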