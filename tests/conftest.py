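import numpy as np
import pytest

from profileseq import FixtureConfig, generate_profile_dataset
from profileseq.fixtures import PeakPlan, generate_annotation_fixture


@pytest.fixture(scope="session")
def enriched_dataset():
    """3-fold enrichment in the 5 central bins, uniform aux tracks."""
    config = FixtureConfig(
        seed=11,
        n_refs=200,
        enrichment_windows=((-2, 2),),
        enrichment_fold=3.0,
        with_aux=True,
    )
    return config, generate_profile_dataset(config)


@pytest.fixture(scope="session")
def annotation_fixture():
    return generate_annotation_fixture(
        seed=7,
        n_transcripts=4,
        exons_per_transcript=5,
        peak_plan=[
            PeakPlan(0, 0, "DS", 500),
            PeakPlan(1, 1, "US", 300),
            PeakPlan(2, 2, "DS", 999),
        ],
        scripted_psi=((3, 3, 1), (5, 5, 5), (4, 0, 2)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
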