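import numpy as np
import pytest

from pepshift import datasets, synth
from pepshift.synth import JitterSpec


@pytest.fixture(scope="session")
def palustrin_seq():
    return datasets.palustrin_ca_sequence()


@pytest.fixture(scope="session")
def palustrin_shifts():
    return datasets.palustrin_ca_shifts()


@pytest.fixture(scope="session")
def ideal_helix(palustrin_seq):
    return synth.build_ideal_helix(palustrin_seq)


@pytest.fixture(scope="session")
def ala20_helix():
    return synth.build_ideal_helix("A" * 20)


@pytest.fixture(scope="session")
def jitter_ensemble(ideal_helix):
    """20-model synthetic ensemble: rigid helix core, mobile termini."""
    sigma = {r: 0.2 for r in range(6, 27)}
    sigma.update({r: 1.2 for r in list(range(1, 6)) + list(range(27, 32))})
    spec = JitterSpec(sigma=sigma, n_frames=20, seed=42)
    return synth.synth_trajectory(ideal_helix, spec).ensemble


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
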