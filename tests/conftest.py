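import numpy as np
import pandas as pd
import pytest

from craave.counting import build_count_matrix
from craave.library import GuideRecord, LibraryDefinition
from craave.simulate import SimulationConfig, simulate_counts, simulate_library


@pytest.fixture
def tiny_library() -> LibraryDefinition:
    """Three genes x 2 guides (one gene TSS-split) plus 2 NTCs."""
    return LibraryDefinition(
        [
            GuideRecord("geneA_sg0", "ACGGTTCAGATCCGGTAATC", "geneA"),
            GuideRecord("geneA_sg1", "TTGACCGTAGGCTTAAGCAC", "geneA"),
            GuideRecord("geneB_sg0", "CCTAGGATTCACGGTCGATA", "geneB", tss_group="P1"),
            GuideRecord("geneB_sg1", "GGATCCTTAGCAAGTCGTTC", "geneB", tss_group="P2"),
            GuideRecord("geneC_sg0", "ACTGCATGGATCGGAATTGC", "geneC"),
            GuideRecord("geneC_sg1", "GTCAAGGTCTTACGCATGGA", "geneC"),
            GuideRecord("ntc_sg0", "AATGCCGATTGGTCAGATTG", "NTC", is_ntc=True),
            GuideRecord("ntc_sg1", "CCGGAATGTTCAGGCATCAG", "NTC", is_ntc=True),
        ]
    )


def make_count_matrix(library, columns, roles):
    """columns: dict sample_id -> per-guide count list in library order."""
    triples = [
        (sid, role, dict(zip(library.guide_ids, counts)))
        for (sid, counts), role in zip(columns.items(), roles)
    ]
    return build_count_matrix(triples, library)


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """Desk-scale screen: strong signal, quick to simulate and analyze."""
    return SimulationConfig(
        n_genes=150,
        n_ntc=60,
        fraction_essential=0.08,
        n_mice=4,
        neurons_per_mouse=20_000,
        reads_per_sample=300_000,
        seed=42,
    )


@pytest.fixture
def small_screen(small_sim_config):
    library, truth = simulate_library(small_sim_config)
    counts = simulate_counts(library, truth, small_sim_config)
    return library, truth, counts
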