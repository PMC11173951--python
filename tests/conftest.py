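import numpy as np
import pytest

from boronpka import AcidSystem


@pytest.fixture
def weak_system() -> AcidSystem:
    """The headline bench system: phenylboronic-acid-like weak acid,
    1e-3 M in 50 mL, titrated with 0.05 M NaOH (equivalence at 1.00 mL)."""
    return AcidSystem(pka=8.76, c_acid=1e-3, v0=50.0, c_base=0.05)


@pytest.fixture
def strong_buffer_system() -> AcidSystem:
    """A well-buffered moderately strong acid (carboxylic-acid-like)."""
    return AcidSystem(pka=5.0, c_acid=0.01, v0=50.0, c_base=0.05)


@pytest.fixture
def fine_schedule(weak_system) -> np.ndarray:
    return np.linspace(0.0, 2.0, 101)
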