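import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from stdgem.synthetic import (
    GenerationConfig, make_complex, make_panel, make_two_state_ensemble,
)


@pytest.fixture(scope="session")
def gen_config():
    return GenerationConfig(seed=0)


@pytest.fixture(scope="session")
def toy_complex(gen_config):
    """Pocket complex with one planted contact of each kind."""
    return make_complex(gen_config)


@pytest.fixture(scope="session")
def panel13(gen_config):
    """Thirteen-compound screening panel with one planted non-binder."""
    return make_panel(gen_config)


@pytest.fixture(scope="session")
def two_state(gen_config):
    """Forty-frame ensemble around two references 5 A apart (sigma 0.2 A)."""
    return make_two_state_ensemble(gen_config)
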