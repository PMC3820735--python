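"""Shared fixtures: a small fully-simulated dataset with ground truth."""

import pytest

from promsig.motif_engine import build_occurrence_matrix, default_motif_library
from promsig.synthetic_data import SimulationConfig, generate_promoters


@pytest.fixture(scope="session")
def small_dataset():
    """300 synthetic promoters: genome, catalog, windows, sequences, truth."""
    config = SimulationConfig(n_promoters=300)
    genome, catalog, windows, seqs, truth = generate_promoters(config, seed=11)
    return {
        "config": config,
        "genome": genome,
        "catalog": catalog,
        "windows": windows,
        "seqs": seqs,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_occurrence(small_dataset):
    return build_occurrence_matrix(small_dataset["seqs"], default_motif_library())
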