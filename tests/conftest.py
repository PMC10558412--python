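import numpy as np
import pytest

from nucleomech.core import IndentationProtocol


@pytest.fixture(scope="session")
def default_protocol() -> IndentationProtocol:
    """The standard amplitude-sweep protocol (0.6-1.6 um, 0.1 um steps,
    0.5 Hz square wave, 45 s per amplitude, 3 um bead)."""
    return IndentationProtocol()


@pytest.fixture(scope="session")
def short_protocol() -> IndentationProtocol:
    """A reduced sweep for fast unit tests (3 amplitudes, 9 s dwell)."""
    return IndentationProtocol(
        amplitudes_um=(0.8, 1.2, 1.6), dwell_per_amplitude_s=9.0
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
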