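"""Shared fixtures: small synthetic datasets generated at test time."""

from pathlib import Path

import pytest

from radploidy.simulate import (
    SimulationConfig,
    emit_files,
    simulate_allotetraploid,
    simulate_parents,
)


@pytest.fixture(scope="session")
def f1_config() -> SimulationConfig:
    """Plain F1 allotetraploid: no backcrossing, no post-origin mutation."""
    return SimulationConfig(n_loci=300, seed=11)


@pytest.fixture(scope="session")
def f1_dataset(f1_config, tmp_path_factory):
    """Simulated F1 dataset emitted to disk once per session."""
    outdir = tmp_path_factory.mktemp("f1")
    _, parent1, parent2 = simulate_parents(f1_config)
    tetraploid, truth = simulate_allotetraploid(parent1, parent2, f1_config)
    files = emit_files(parent1, parent2, tetraploid, truth, f1_config, outdir)
    return {
        "config": f1_config,
        "parent1": parent1,
        "parent2": parent2,
        "tetraploid": tetraploid,
        "truth": truth,
        "files": files,
    }


@pytest.fixture(scope="session")
def mixed_config() -> SimulationConfig:
    """Dataset with backcrossing, post-origin mutation and parental het."""
    return SimulationConfig(
        n_loci=500,
        seed=17,
        backcross_fraction=0.2,
        post_origin_rate=0.002,
        parental_heterozygosity=0.002,
    )


@pytest.fixture(scope="session")
def mixed_dataset(mixed_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("mixed")
    _, parent1, parent2 = simulate_parents(mixed_config)
    tetraploid, truth = simulate_allotetraploid(parent1, parent2, mixed_config)
    files = emit_files(parent1, parent2, tetraploid, truth, mixed_config, outdir)
    return {
        "config": mixed_config,
        "parent1": parent1,
        "parent2": parent2,
        "tetraploid": tetraploid,
        "truth": truth,
        "files": files,
    }
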