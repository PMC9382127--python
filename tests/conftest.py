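from __future__ import annotations

from importlib import resources

import pytest

from famdup import annotation_io as aio
from famdup.synthetic_data import SimConfig, simulate_genome


def _pairs_fixture(name: str) -> list[tuple[str, str]]:
    text = resources.files("famdup.data").joinpath(name).read_text()
    pairs = []
    for line in text.splitlines()[1:]:
        a, b = line.split("\t")
        pairs.append((a, b))
    return pairs


@pytest.fixture(scope="session")
def family_table():
    return aio.bundled_family_table()


@pytest.fixture(scope="session")
def tandem_pairs_fixture():
    """The 17 published tandem duplicate pairs."""
    return _pairs_fixture("tandem_pairs.tsv")


@pytest.fixture(scope="session")
def segmental_pairs_fixture():
    """The 15 published segmental duplicate pairs."""
    return _pairs_fixture("segmental_pairs.tsv")


@pytest.fixture(scope="session")
def never_expressed_fixture():
    text = resources.files("famdup.data").joinpath("never_expressed_control.txt").read_text()
    return text.split()


@pytest.fixture(scope="session")
def sim_genome():
    """Default-scale synthetic genome shared across tests (seeded)."""
    return simulate_genome(SimConfig(seed=11))
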