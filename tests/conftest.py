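import numpy as np
import pytest

from cofkit import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_pocket():
    """Single-chain pocket with two donors at 0.74 A planted offsets."""
    spec = sd.PocketSpec(n_donors=2, planted_pi_offsets=(0.74, 0.74),
                         n_metals=1, chains=1, seed=7)
    model, truth = sd.make_pocket(spec)
    return model, truth


def random_structure(rng, n_atoms=100):
    """A random all-atom model for round-trip tests."""
    from cofkit.structgeom import Atom, StructureModel
    elements = ["C", "N", "O", "P", "S"]
    atoms = []
    for i in range(n_atoms):
        el = elements[rng.integers(0, len(elements))]
        atoms.append(Atom(
            serial=i + 1, name=f"{el}{i % 9}", element=el, alt_loc="",
            chain="A", res_name="GLY", res_num=1 + i // 4,
            insertion_code="",
            coords=tuple(np.round(rng.uniform(-99, 99, 3), 3)),
            occupancy=round(float(rng.uniform(0.2, 1.0)), 2),
            is_hetero=bool(rng.random() < 0.2)))
    # hetero flags must be residue-consistent for PDB grouping
    by_res = {}
    for a in atoms:
        by_res.setdefault(a.res_num, a.is_hetero)
    from dataclasses import replace
    atoms = [replace(a, is_hetero=by_res[a.res_num]) for a in atoms]
    return StructureModel(atoms=atoms, title="random model")
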