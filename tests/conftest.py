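import warnings

import numpy as np
import pandas as pd
import pytest

from transkingdom.io import PipelineConfig
from transkingdom.synthetic import GroundTruth, StudyDesign, default_truth, generate_study

# the generators emit bookkeeping warnings (filtered-set mismatches etc.)
# that are irrelevant to most tests
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def desk_config() -> PipelineConfig:
    """Pipeline config matched to the synthetic library sizes."""
    return PipelineConfig(rarefaction_depth=10_000)


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    return StudyDesign(seed=11, n_otus=40)


@pytest.fixture(scope="session")
def planted_study(small_design):
    """A seeded study with the canonical planted scenario."""
    return generate_study(small_design, default_truth(small_design))


@pytest.fixture(scope="session")
def null_study():
    """A study with no planted effects or edges."""
    design = StudyDesign(seed=23, n_otus=40)
    return generate_study(design, GroundTruth())


@pytest.fixture(scope="session")
def fitted_results(planted_study, desk_config):
    from transkingdom.model import TranskingdomModel

    model = TranskingdomModel.from_study(planted_study, config=desk_config)
    return model.fit(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
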