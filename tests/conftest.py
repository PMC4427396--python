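import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mollimap.bloch import TissueParams
from mollimap.sequences import MOLLIProtocol


@pytest.fixture
def protocol() -> MOLLIProtocol:
    """Standard 3(3)3(3)5 protocol at 60 bpm."""
    return MOLLIProtocol()


@pytest.fixture
def myocardium() -> TissueParams:
    return TissueParams(t1=1180.0, t2=45.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240517)
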