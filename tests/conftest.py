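"""Shared fixtures: small simulated data sets and the replicate batteries."""

from __future__ import annotations

import pytest

from hybridly.pipeline import run_pipeline
from hybridly.simulate import SimConfig, simulate_all

N_REPLICATES = 20


@pytest.fixture(scope="session")
def default_replicates():
    """Twenty seeded default pipeline runs (the recovery battery).

    Shared across acceptance criteria so the battery is computed once.
    """
    return [
        run_pipeline(SimConfig(seed=seed), include_aaf=True)
        for seed in range(N_REPLICATES)
    ]


@pytest.fixture(scope="session")
def control_replicates():
    """Twenty negative-control runs: the 'hybrid' is a reference clone."""
    return [
        run_pipeline(
            SimConfig(seed=seed, hybrid_mode="clone"),
            include_its=False,
            include_aaf=False,
        )
        for seed in range(N_REPLICATES)
    ]


@pytest.fixture(scope="session")
def small_sim():
    """One small, fast simulated data set for unit-level checks."""
    cfg = SimConfig(seed=11, n_contigs=1, contig_length=6_000, coverage=20.0)
    return simulate_all(cfg)
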