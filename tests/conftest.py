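"""Shared fixtures: a small simulated study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from scafeval.simulate import (
    OPTICALMAP_LIKE,
    PROXIMITY_LIKE,
    SimConfig,
    fragment,
    simulate_accession,
    simulate_reference,
    simulate_scaffolding,
)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(
        genome_size=8_000_000,
        n_chromosomes=4,
        mean_contig=120_000,
        n_extra_novel=20,
        extra_novel_mean=8_000,
        seed=5,
    )


@pytest.fixture(scope="session")
def sim_bundle(sim_config):
    """reference, accession, base assembly and both scaffolding rounds."""
    rng = np.random.default_rng(sim_config.seed)
    ref = simulate_reference(sim_config, rng)
    acc = simulate_accession(ref, sim_config, rng)
    base = fragment(acc, sim_config, rng)
    optical = simulate_scaffolding(base, OPTICALMAP_LIKE, sim_config, rng)
    proximity = simulate_scaffolding(base, PROXIMITY_LIKE, sim_config, rng)
    return {
        "config": sim_config,
        "reference": ref,
        "accession": acc,
        "base": base,
        "optical": optical,
        "proximity": proximity,
    }
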