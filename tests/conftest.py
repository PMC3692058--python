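import numpy as np
import pytest

from ribotherm import RnaSequence, register_provider
from ribotherm.sequences import TemperatureRange


@pytest.fixture(scope="session")
def default_range() -> TemperatureRange:
    return TemperatureRange(32, 39)


def _constant_provider(seq, t, opts):
    return np.full(len(seq), 0.5)


def _ramp_provider(seq, t, opts):
    """p grows linearly with temperature at one position, flat elsewhere."""
    p = np.full(len(seq), 0.2)
    p[len(seq) // 2] = min(1.0, 0.2 + 0.01 * (t - 32))
    return p


def _step_provider(seq, t, opts):
    """0.3 jump at position 1 (1-based) only at the top temperature 39."""
    p = np.zeros(len(seq))
    if t == 39:
        p[0] = 0.3
    return p


register_provider("test-constant", _constant_provider)
register_provider("test-ramp", _ramp_provider)
register_provider("test-step", _step_provider)


@pytest.fixture
def hairpin_seq() -> RnaSequence:
    return RnaSequence(id="hp", residues="GGGGGAAAAACCCCC")
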