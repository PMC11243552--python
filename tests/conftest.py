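import numpy as np
import pytest

from bindscape.binding_mode import BindingFingerprint
from bindscape.fixtures import ComplexPlantSpec, ContactPlant, synth_complex
from bindscape.ligands import Ligand, enumerate_designed_ligands


@pytest.fixture(scope="session")
def designed_library():
    return enumerate_designed_ligands()


@pytest.fixture
def plain_ligand():
    """Helper factory for ad-hoc ligands from a SMILES string."""

    def make(smiles, lig_id="lig", conformer=None):
        return Ligand(
            id=lig_id,
            series="none",
            substituents={"R1": "H", "R2": "H", "R3": "H", "R4": "H"},
            structure=smiles,
            conformer=conformer,
        )

    return make


@pytest.fixture(scope="session")
def narrated_complex():
    """Toy complex planting the co-crystal geometries reported for the
    kinase targets: a near-linear N-H...O hydrogen bond (3.14 A), a long
    non-linear O-H...O bond (3.81 A / 102.05 deg), a strong Br...O
    halogen bond (3.0 A / 172.68 deg) and a hydrophobic contact in the
    3.47-3.95 A range."""
    spec = ComplexPlantSpec(
        plants=[
            ContactPlant("hbond", 3.14, 165.0, "ASN"),
            ContactPlant("hbond", 3.81, 102.05, "ASN"),
            ContactPlant("halogen_bond", 3.0, 172.68, "VAL"),
            ContactPlant("hydrophobic", 3.9, None, "LEU"),
        ]
    )
    cx, pdb_text = synth_complex(spec)
    return spec, cx, pdb_text


def random_fingerprint(rng, n_keys=8, key_pool=None, source="contacts"):
    keys = key_pool or [f"RES{i}" for i in range(20)]
    chosen = rng.choice(len(keys), size=min(n_keys, len(keys)), replace=False)
    entries = {keys[i]: float(rng.normal(scale=5)) for i in chosen}
    return BindingFingerprint(ligand_id="x", entries=entries, source=source)
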