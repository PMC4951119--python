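import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from brainmarkers.datamodel import REGIONS, ExpressionDataset
from brainmarkers.simulate import DEFAULT_COUNTS, DEFAULT_INDIVIDUALS


def make_dataset(individual_id, counts, n_genes=3, seed=0, gene_ids=None):
    """A small random dataset with the given (BS, CB, CC) sample counts."""
    rng = np.random.default_rng(seed)
    s = sum(counts)
    labels = [r for r, c in zip(REGIONS, counts) for _ in range(c)]
    return ExpressionDataset(
        individual_id=individual_id,
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        sample_ids=[f"{individual_id}_s{j}" for j in range(s)],
        values=rng.normal(size=(n_genes, s)),
        region_labels=labels,
    )


@pytest.fixture
def table1_cohort():
    """Six datasets whose per-region sample counts mirror the study design."""
    return [
        make_dataset(ind, counts, n_genes=2, seed=i)
        for i, (ind, counts) in enumerate(zip(DEFAULT_INDIVIDUALS, DEFAULT_COUNTS))
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A fast planted cohort shared by classifier/IFS tests."""
    from brainmarkers.simulate import GeneratorConfig, generate_cohort

    config = GeneratorConfig(
        n_genes=200,
        per_individual_counts=((10, 12, 30), (8, 10, 25), (12, 9, 28)),
        individual_ids=("A", "B", "C"),
        n_planted_per_region=5,
        effect_size=2.0,
        seed=7,
    )
    return generate_cohort(config)
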