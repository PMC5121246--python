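"""Shared fixtures: one small synthetic experiment reused across modules."""

from __future__ import annotations

import pytest
from hypothesis import settings

from srnatransfer.filtering import screen_library, length_filter
from srnatransfer.io_formats import ROLES, read_sequences
from srnatransfer.set_pipeline import collapse
from srnatransfer.synthetic_data import (
    SimulationConfig,
    generate_experiment,
    generate_references,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        seed=11,
        reads_per_library={role: 8_000 for role in ROLES},
        n_plant_loci=5,
        locus_length=2_000,
        n_transcripts=20,
        n_insect_only=200,
        n_transferred=30,
        n_egg_specific=15,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_experiment(tmp_path_factory):
    """Small default experiment: (config, references, role->path, truth)."""
    config = small_config()
    references = generate_references(config)
    outdir = tmp_path_factory.mktemp("sim")
    paths, truth = generate_experiment(config, references, outdir)
    return config, references, paths, truth


@pytest.fixture(scope="session")
def filtered_libraries(sim_experiment):
    """The six libraries after length filter, collapsing and contaminant screens."""
    _, references, paths, _ = sim_experiment
    screens = [references[c] for c in ("virus", "ncrna", "transcriptome")]
    libraries = {}
    for role, path in paths.items():
        records = read_sequences(path, format="fastq")
        retained, _ = length_filter(records)
        clean, _ = screen_library(collapse(retained, role), screens)
        libraries[role] = clean
    return libraries
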