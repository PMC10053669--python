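import numpy as np
import pytest

import mechbond as mb

from helpers import five_mode_specs


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def five_mode_config():
    return mb.GeneratorConfig(
        n_residues_per_chain=5,
        bond_specs=five_mode_specs(),
        n_frames=2000,
        seed=11,
    )


@pytest.fixture
def two_bond_trajectory():
    """A small complex with one catch-slip and one steady planted bond."""
    specs = [
        mb.BondSpec(("A", 1, "N", "H"), ("B", 1, "O"), "catch_slip",
                    0.2, (0.5,), (50.0,), (20.0,), "b1"),
        mb.BondSpec(("A", 2, "N", "H"), ("B", 2, "O"), "steady", 0.5,
                    label="b2"),
    ]
    cfg = mb.GeneratorConfig(
        n_residues_per_chain=3, bond_specs=specs, n_frames=500, seed=7
    )
    structure = mb.generate_complex(cfg)
    traj = mb.generate_trajectory(structure, cfg, 50.0)
    return cfg, structure, traj
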