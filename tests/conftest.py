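import json
from importlib import resources

import numpy as np
import pytest

from emadiary.item_bank import load_default_bank


@pytest.fixture(scope="session")
def bank():
    return load_default_bank()


@pytest.fixture(scope="session")
def bank_document():
    """The packaged default bank as a mutable dict, for invalid-document tests."""
    text = resources.files("emadiary.data").joinpath("default_bank.json").read_text("utf-8")
    return json.loads(text)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
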