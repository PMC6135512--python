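"""Shared fixtures: small toy-dimer systems built by the synthetic module."""

import numpy as np
import pytest

from dimertraj import SyntheticSpec, build_toy_dimer


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest convenient dimer: 16 residues/monomer, short loop."""
    return SyntheticSpec(residues_per_monomer=16, loop_range=(3, 4),
                         n_frames=100, seed=1)


@pytest.fixture(scope="session")
def tiny_system(tiny_spec):
    return build_toy_dimer(tiny_spec)


@pytest.fixture(scope="session")
def full_size_system():
    """Dimer with the real enzyme's residue count (1-413 per monomer)."""
    spec = SyntheticSpec(seed=1)
    return build_toy_dimer(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1)
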