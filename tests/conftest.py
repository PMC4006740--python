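"""Shared fixtures: small pedigrees and one emitted simulation bundle."""

from __future__ import annotations

import pytest

from ibdmap.pedigree import Affection, Individual, Pedigree, Sex
from ibdmap.simulate import SimulationConfig, emit_dataset, simulate_dataset


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree(
        [
            Individual("dad", sex=Sex.MALE),
            Individual("mom", sex=Sex.FEMALE),
            Individual("kid", "dad", "mom", Sex.FEMALE, Affection.AFFECTED),
        ],
        family_id="TRIO",
    )


@pytest.fixture
def sib_pedigree() -> Pedigree:
    """Two full sibs plus an inbred child of the sib union."""
    return Pedigree(
        [
            Individual("gf", sex=Sex.MALE),
            Individual("gm", sex=Sex.FEMALE),
            Individual("s1", "gf", "gm", Sex.MALE),
            Individual("s2", "gf", "gm", Sex.FEMALE),
            Individual("kid", "s1", "s2"),
        ],
        family_id="SIBS",
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """One default-parameter simulation (seed 1), shared across tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_bundle(sim_dataset, tmp_path_factory):
    """The same simulation, emitted to disk as the pipeline file bundle."""
    out = tmp_path_factory.mktemp("bundle")
    paths = emit_dataset(sim_dataset, out)
    return sim_dataset, paths
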