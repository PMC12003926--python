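"""Shared fixtures: toy models and one session-scoped benchmark run."""

from __future__ import annotations

import numpy as np
import pytest

from bacascan.classify import FamilySeeds, PipelineConfig, classify_all
from bacascan.io_formats import SeedAlignment
from bacascan.profile_hmm import ProfileHMM, build_profile
from bacascan.synthetic_data import SimConfig, generate_benchmark, score_recovery


def random_profile(rng: np.random.Generator, n_match: int) -> ProfileHMM:
    """A valid random profile HMM for property tests."""
    me = rng.dirichlet(np.full(20, 0.5), size=n_match)
    me = np.clip(me, 1e-6, None)
    me /= me.sum(axis=1, keepdims=True)
    tr = np.empty((n_match, 7))
    for k in range(n_match):
        m = rng.dirichlet([8.0, 1.0, 1.0])
        i = rng.dirichlet([3.0, 1.0])
        d = rng.dirichlet([3.0, 1.0])
        tr[k] = np.concatenate([m, i, d])
    return ProfileHMM(family_name="rand", match_emissions=me, transitions=tr)


@pytest.fixture(scope="session")
def toy_seed() -> SeedAlignment:
    return SeedAlignment(
        [f"r{i}" for i in range(4)],
        ["MKVLAW", "MKVLAW", "MKVIAW", "MKV-AW"],
    )


@pytest.fixture(scope="session")
def toy_hmm(toy_seed) -> "ProfileHMM":
    return build_profile(toy_seed, family_name="toy")


@pytest.fixture(scope="session")
def benchmark_run():
    """One full pipeline run on the default benchmark (60 species, five
    families, emission divergence 0.25, 20 decoys per species)."""
    bench = generate_benchmark(SimConfig(seed=1))
    cfg = PipelineConfig(n_calib=300, seed=101)
    result = classify_all(
        bench.proteins,
        bench.species_table,
        FamilySeeds(bench.mining_seed, bench.family_seeds),
        cfg,
    )
    recovery = score_recovery(result.finals, bench.truth, result.ssn.component_of)
    return bench, result, recovery
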