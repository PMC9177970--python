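"""Shared fixtures: deterministic hexamer tables and small synthetic studies."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from splicecode.formats import HexamerEntry, HexamerTable
from splicecode.synthetic import SimulationConfig, simulate_efhand_genes

ALL_HEXAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=6)]


@pytest.fixture(scope="session")
def toy_table() -> HexamerTable:
    """Full 4096-hexamer table with reproducible scores and rule-based labels
    (ESE iff the hexamer starts with GA, ESS iff it starts with CC)."""
    rng = np.random.default_rng(42)
    entries = {}
    for h in ALL_HEXAMERS:
        if h.startswith("GA"):
            label = "ESE"
        elif h.startswith("CC"):
            label = "ESS"
        else:
            label = "NEUTRAL"
        entries[h] = HexamerEntry(float(rng.normal()), label)
    return HexamerTable(entries)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_canonical=40, n_noncanonical=10,
                            n_s100=5, n_control_exons=60)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_efhand_genes(small_config)
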