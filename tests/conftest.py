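"""Shared fixtures: the seeded default synthetic benchmark."""

from __future__ import annotations

import pytest

from srnapipe.simulate import (
    SimulationConfig,
    simulate_degradome,
    simulate_small_rna_libraries,
    simulate_transcriptome,
)

BENCH_SEED = 1


@pytest.fixture(scope="session")
def bench_config() -> SimulationConfig:
    return SimulationConfig(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def bench(bench_config):
    """Default synthetic benchmark: transcripts, truth, small-RNA + degradome libraries."""
    records, truth = simulate_transcriptome(bench_config)
    libraries = simulate_small_rna_libraries(truth, bench_config)
    degradome = simulate_degradome(truth, bench_config)
    return {
        "config": bench_config,
        "records": records,
        "truth": truth,
        "libraries": libraries,
        "degradome": degradome,
        "seq_by_id": {r.id: r.sequence for r in records},
    }


@pytest.fixture(scope="session")
def bench_tag_union(bench):
    union: dict[str, int] = {}
    for lib in bench["libraries"]:
        for tag, cnt in lib.tags.items():
            union[tag] = union.get(tag, 0) + cnt
    return union
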