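import numpy as np
import pytest
from hypothesis import settings

from egaflow.io_tables import SampleDesign, Source, Stage
from egaflow.synthetic_data import GeneClass, SimConfig, default_design, simulate_counts

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def paper_design() -> SampleDesign:
    """Six samples: 2-cell 1 ivv + 2 ivt; 4-cell 2 ivv + 1 ivt."""
    return default_design()


@pytest.fixture
def two_sample_design() -> SampleDesign:
    """One sample per stage, single source (two-group comparisons)."""
    return SampleDesign(
        sample_ids=["s2", "s4"],
        stages=[Stage.TWO_CELL, Stage.FOUR_CELL],
        sources=[Source.IN_VIVO, Source.IN_VIVO],
        replicates=["1", "1"],
    )


@pytest.fixture
def six_equal_design() -> SampleDesign:
    """Three samples per stage, single source, for equal-offset oracles."""
    return SampleDesign(
        sample_ids=[f"s{i}" for i in range(6)],
        stages=[Stage.TWO_CELL] * 3 + [Stage.FOUR_CELL] * 3,
        sources=[Source.IN_VIVO] * 6,
        replicates=["1", "2", "3", "1", "2", "3"],
    )


@pytest.fixture(scope="session")
def high_count_sim():
    """A matrix with counts in the hundreds-to-thousands for recovery tests."""
    config = SimConfig(n_genes=1000, baseline_log_rate_mean=-8.0, seed=7)
    return simulate_counts(config)


@pytest.fixture(scope="session")
def null_only_poisson_sim():
    """Pure-Poisson matrix of null genes with equal rates and libraries."""
    config = SimConfig(
        n_genes=2000,
        class_proportions={GeneClass.NULL: 1.0},
        baseline_log_rate_sd=0.0,
        baseline_log_rate_mean=-11.0,
        dispersion=1.0,
        library_sizes=(2_000_000,) * 6,
        seed=42,
    )
    return simulate_counts(config)


def truth_to_expected_category(gene_class: GeneClass):
    from egaflow.categorize import TranscriptCategory

    return {
        GeneClass.TWO_CELL_ONLY: TranscriptCategory.TWO_CELL_ONLY,
        GeneClass.TWO_CELL_ENRICHED: TranscriptCategory.TWO_CELL_ENRICHED,
        GeneClass.FOUR_CELL_ENRICHED: TranscriptCategory.FOUR_CELL_ENRICHED,
        GeneClass.FOUR_CELL_ONLY: TranscriptCategory.FOUR_CELL_ONLY,
        GeneClass.NULL: TranscriptCategory.NOT_DE,
    }[gene_class]
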