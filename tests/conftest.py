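import numpy as np
import pytest

from patterntransfer.io_formats import ExpressionMatrix, SampleAnnotation
from patterntransfer.synthetic_data import SyntheticScenario, generate_scenario


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = rng.random((6, 4)) * 10
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(6)],
        sample_ids=[f"s{j}" for j in range(4)],
        values=values,
    )


@pytest.fixture
def small_bundle():
    """A small but fully structured two-species scenario (fast to generate)."""
    scenario = SyntheticScenario(genes_per_species=300, marker_genes_per_pattern=15, seed=11)
    return generate_scenario(scenario)


@pytest.fixture
def noise_free_bundle():
    scenario = SyntheticScenario(
        genes_per_species=300,
        marker_genes_per_pattern=15,
        noise_sd=0.0,
        depth_factor_sd=0.0,
        sample_effect_sd=0.0,
        jitter_max=0.0,
        seed=5,
    )
    return generate_scenario(scenario)


def make_annotations(
    sample_ids,
    tissues,
    states,
    dataset="d1",
    library_sizes=None,
):
    return [
        SampleAnnotation(
            sample_id=s,
            dataset=dataset,
            tissue=t,
            state=st,
            library_size=None if library_sizes is None else library_sizes[i],
        )
        for i, (s, t, st) in enumerate(zip(sample_ids, tissues, states))
    ]
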