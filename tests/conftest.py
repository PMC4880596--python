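import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from neuroplast.plasticity import SynapseRule, SynapseStore


@pytest.fixture
def simple_store():
    return SynapseStore(
        [
            SynapseRule("ex_syn", "Axon_ex", "Den_ex", amplitude=1.0, delay=1.0),
            SynapseRule("in_syn", "Axon_in", "Den_in", amplitude=-1.0, delay=1.0),
        ]
    )
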