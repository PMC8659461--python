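import numpy as np
import pytest

import gazeload as gl
from gazeload.classifiers import CVScheme
from gazeload.features import WindowSpec, build_feature_table
from gazeload.pipeline import ExperimentConfig, _segment_channel

STUDY_SEED = 11


@pytest.fixture(scope="session")
def default_study():
    """Full default two-class study: 30 subjects x 12 x 60 s segments."""
    return gl.simulate_study(gl.GazeSimSpec(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def default_events(default_study):
    return _segment_channel(default_study, ExperimentConfig(), "eyeT")


@pytest.fixture(scope="session")
def feature_table(default_study, default_events):
    """The 720-window, 13-feature table of the default study."""
    return build_feature_table(
        default_events,
        WindowSpec(30.0),
        [s.label for s in default_study],
        [s.subject_id for s in default_study],
        segment_duration=60.0,
    )


@pytest.fixture(scope="session")
def cv5():
    return CVScheme(method="kfold", k=5, seed=STUDY_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(STUDY_SEED)
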