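import numpy as np
import pytest

from rigidbd.io_formats import AtomRecord, Structure


def random_body(n: int, seed: int, spread: float = 5.0, element: str = "C",
                lj_rmin_half: float = 2.0, lj_epsilon: float = 0.1) -> Structure:
    """A seeded random rigid body with +-charges and uniform LJ parameters."""
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n):
        atoms.append(AtomRecord(
            serial=i + 1, name=f"A{i}", element=element, residue_name="TOY",
            residue_id=i + 1, chain="A",
            position=tuple(rng.uniform(-spread, spread, 3)),
            charge=float(rng.choice([-1.0, 1.0]) * rng.uniform(0.2, 1.0)),
            lj_rmin_half=lj_rmin_half, lj_epsilon=lj_epsilon, vdw_radius=1.7,
        ))
    return Structure(atoms)


def single_atom(position=(0.0, 0.0, 0.0), charge=1.0, rmin_half=2.0, eps=0.1,
                serial=1, element="C", name="A0", residue_id=1) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name="ONE", residue_id=residue_id, chain="A",
                      position=tuple(position), charge=charge,
                      lj_rmin_half=rmin_half, lj_epsilon=eps, vdw_radius=1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
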