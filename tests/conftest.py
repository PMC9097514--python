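import pytest

from formurs import (REPORTED_TERM_SETS, ModelSpec, fit_ols,
                     load_test_design, load_training_design)


@pytest.fixture(scope="session")
def train():
    return load_training_design()


@pytest.fixture(scope="session")
def test_set():
    return load_test_design()


@pytest.fixture(scope="session")
def reported_models(train):
    """The four reduced response-surface models refit on the training runs."""
    return {resp: fit_ols(train, ModelSpec.from_strings(resp, terms))
            for resp, terms in REPORTED_TERM_SETS.items()}
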