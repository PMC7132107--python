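import numpy as np
import pytest

from helixswitch.state_builder import (build_long_state, build_short_state,
                                       default_architecture)


@pytest.fixture(scope="session")
def spec():
    return default_architecture()


@pytest.fixture(scope="session")
def short_model(spec):
    return build_short_state(spec)


@pytest.fixture(scope="session")
def long_model(spec):
    return build_long_state(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    from helixswitch.io import generate_fixtures
    out = tmp_path_factory.mktemp("fixtures")
    files = generate_fixtures(seed=11, outdir=out)
    return files


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
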