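import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from karyofish import fixtures as fx


@pytest.fixture(scope="session")
def manifest():
    return fx.load_manifest()


@pytest.fixture(scope="session")
def reference():
    return fx.load_reference()


@pytest.fixture(scope="session")
def event_matrix():
    return fx.load_event_matrix()


@pytest.fixture(scope="session")
def pattern_matrix():
    return fx.load_pattern_matrix()
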