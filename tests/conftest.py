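import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import somnarc as sa


@pytest.fixture(scope="session")
def default_bundle():
    """One default 3-h synthetic recording shared across tests (seed 0)."""
    return sa.generate_recording(sa.SynthParams(seed=0))


@pytest.fixture(scope="session")
def scored_hypnogram(default_bundle):
    return sa.reclassify_microarousals(default_bundle["hypnogram"])


def hypnogram_from_string(s: str, epoch_length: float = 4.0) -> sa.Hypnogram:
    """Compact builder: 'NNNWWN' -> Hypnogram."""
    return sa.Hypnogram(np.array(list(s)), epoch_length=epoch_length)
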