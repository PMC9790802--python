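import numpy as np
import pytest

from sedcarbon import MixingParams, SurveySpec, generate_survey, samples_to_frame

#: parameter set used throughout: the literature-mean self-packing densities
FIG_PARAMS = MixingParams(0.09, 1.75, 2.2)


@pytest.fixture(scope="session")
def fig_params() -> MixingParams:
    return FIG_PARAMS


@pytest.fixture(scope="session")
def param_grid() -> list[MixingParams]:
    """Three plausible parameterisations spanning the reported range."""
    return [
        MixingParams(0.09, 1.75, 2.2),
        MixingParams(0.085, 1.65, 2.2),
        MixingParams(0.10, 2.00, 2.0),
    ]


@pytest.fixture(scope="session")
def survey_frame():
    """One default synthetic survey as a tidy DataFrame (seed-fixed)."""
    samples = generate_survey(SurveySpec(seed=42))
    return samples_to_frame(samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
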