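"""Shared fixtures: small simulated libraries with ground truth.

Everything is generated programmatically at test time; nothing is read from
disk.  Session scope keeps the medium-sized simulations to one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from midseq.preprocess import PreprocessConfig, prepare_reads
from midseq.simulate import SimConfig, simulate_reads


def make_prepared(truth_config: SimConfig, sim_reads):
    """Prepared reads for a simulation, asserting nothing is silently lost."""
    prep = prepare_reads(sim_reads.reads, PreprocessConfig(
        anchor=truth_config.anchor, mid_length=truth_config.mid_length,
    ))
    return prep


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free small library: 40 clones, 3 copies/cell, 15x coverage."""
    config = SimConfig(
        K=40, alpha=2.5, m=3, seed=101,
        pcr_error_rate=0.0, seq_error_rate=0.0,
        reads_per_molecule_mean=15.0,
    )
    truth, reads = simulate_reads(config)
    return config, truth, reads


@pytest.fixture(scope="session")
def noisy_sim():
    """Realistic small library: PCR + sequencing errors at default rates."""
    config = SimConfig(
        K=150, alpha=2.5, m=3, seed=202,
        reads_per_molecule_mean=30.0,
    )
    truth, reads = simulate_reads(config)
    return config, truth, reads


@pytest.fixture(scope="session")
def noisy_prepared(noisy_sim):
    config, truth, reads = noisy_sim
    return config, truth, make_prepared(config, reads).prepared


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
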