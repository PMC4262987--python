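"""Shared fixtures: random sequence helpers and cached pipeline runs."""

from __future__ import annotations

import random

import pytest

from coremum.pipeline import RunConfig, run_align
from coremum.sequence_io import Genome
from coremum.simulate import SimConfig, simulate_evolution


def random_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def mutate_seq(rng: random.Random, seq: str, n_mut: int) -> str:
    s = list(seq)
    for _ in range(n_mut):
        s[rng.randrange(len(s))] = rng.choice("ACGT")
    return "".join(s)


@pytest.fixture(scope="session")
def rng() -> random.Random:
    return random.Random(20240901)


@pytest.fixture(scope="session")
def run8():
    """A small but complete study: 8 genomes, 30 kb, medium divergence,
    a few rearrangements; shared across tests that only need 'a run'."""
    config = SimConfig(
        length=30_000, leaves=8, rate=1e-4, n_rearrangements=3,
        rearrangement_size=800, seed=2024,
    )
    genomes, truth = simulate_evolution(config)
    result = run_align(genomes, config=RunConfig(seed=7))
    return genomes, truth, result


@pytest.fixture(scope="session")
def bench_run():
    """Cached full-protocol runs keyed by substitution rate: 32 genomes,
    100 kb ancestor, balanced tree, ~10 x 1 kb rearrangements per genome."""
    cache: dict[float, tuple] = {}

    def factory(rate: float, n_rearrangements: float = 10.0, leaves: int = 32):
        key = (rate, n_rearrangements, leaves)
        if key not in cache:
            config = SimConfig(
                length=100_000, leaves=leaves, rate=rate, tstv=4.0,
                n_rearrangements=n_rearrangements, rearrangement_size=1000,
                seed=4242,
            )
            genomes, truth = simulate_evolution(config)
            result = run_align(genomes, config=RunConfig(seed=11))
            cache[key] = (genomes, truth, result)
        return cache[key]

    return factory


def toy_genome(gid: str, seq: str) -> Genome:
    return Genome(id=gid, contigs=[("chr", seq)])
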