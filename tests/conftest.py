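import numpy as np
import pytest

from tcrlens.synthetic import (
    PlantedContact,
    ToyComplexSpec,
    make_toy_complex,
    _Builder,
    _add_chain_trace,
    _centered_xs,
)


@pytest.fixture(scope="session")
def toy_complex():
    """Default toy complex: 45 deg crossing angle, centred footprint."""
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_complex_with_contacts():
    """Toy complex with one planted HB (peptide), one vdW (peptide) and one
    salt bridge (HLA alpha1 helix)."""
    spec = ToyComplexSpec(
        crossing_angle=60.0,
        footprint_offset=(2.0, -1.0),
        seed=7,
        planted_contacts=[
            PlantedContact(kind="hb", distance=2.9, target="peptide", target_index=1),
            PlantedContact(kind="vdw", distance=3.6, target="peptide", target_index=5),
            PlantedContact(kind="sb", distance=3.2, target="hla", target_index=4,
                           tcr_chain="E"),
        ],
    )
    return make_toy_complex(spec)


def single_chain_trace(n_residues: int, chain: str = "D"):
    """Helix-like C-alpha trace, one atom per residue: a minimal protein
    for ensemble statistics (non-collinear, so superposition is well
    conditioned)."""
    b = _Builder()
    i = np.arange(n_residues)
    coords = np.column_stack([
        i * 1.5,
        5.0 * np.cos(0.6 * i),
        5.0 * np.sin(0.6 * i),
    ])
    _add_chain_trace(b, chain, coords)
    return b.build()


@pytest.fixture(scope="session")
def chain120():
    return single_chain_trace(120)
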