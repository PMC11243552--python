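"""Synthetic fixtures and packaged docking-energy tables.

Two generators make the toolkit testable without external engines:

* :func:`synth_complex` builds a minimal protein/ligand complex in which
  each requested contact (hydrogen bond, halogen bond, hydrophobic) is
  planted at an exact distance and angle, and writes it as a
  standards-conforming PDB;
* :func:`synth_landscape` builds a synthetic (similarity, affinity)
  dataset with planted activity cliffs on top of a seeded random
  background.

:func:`load_packaged_tables` ships verbatim transcriptions of the
docking-energy tables for the three kinase targets (CK2alpha, PIM-1,
RIO1) as package data, checksum-pinned.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from bindscape.binding_mode import EnergyRecord, ingest_energy_table
from bindscape.interactions import Atom, ComplexStructure
from bindscape.landscape import ActivityRecord
from bindscape.ligands import SimilarityMatrix

__all__ = [
    "ContactPlant",
    "ComplexPlantSpec",
    "LandscapePlantSpec",
    "synth_complex",
    "synth_landscape",
    "write_pdb",
    "load_packaged_tables",
    "packaged_table_checksum",
    "PACKAGED_TABLES",
    "PACKAGED_SHA256",
]

PACKAGED_TABLES = ("ck2a", "pim1", "rio1")
PACKAGED_SHA256 = {
    "ck2a": "30b7ab16c5eab9f128698007d1bff594df38938279c647e5dc2cebd363c11044",
    "pim1": "3677a59e907ed46f3d009aa9d8d410119a063819a9f3ec1f9037d363032289b1",
    "rio1": "a77a6b1fd1408daad75124ba26caabce5d80071fe5195bd26eff8b611d8a3d49",
}
# Series of the ligands in each packaged table (the single-series tables
# do not carry a glycone column).
_TABLE_SERIES = {"ck2a": None, "pim1": "difluoro", "rio1": "difluoro"}


@dataclass
class ContactPlant:
    """One contact to plant: kind, target geometry, hosting residue."""

    kind: str  # hbond | halogen_bond | hydrophobic
    distance: float
    angle: float | None = None
    residue_name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"hbond", "halogen_bond", "hydrophobic"}:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("plant distance must be > 0")
        if self.angle is not None and not (0 <= self.angle <= 180):
            raise ValueError("plant angle must lie in [0,180]")
        if self.kind == "hbond" and self.distance <= 1.05:
            raise ValueError("hbond plant infeasible: donor-acceptor distance <= D-H bond length")
        if self.residue_name is None:
            self.residue_name = {"hbond": "ASN", "halogen_bond": "VAL", "hydrophobic": "LEU"}[
                self.kind
            ]


@dataclass
class ComplexPlantSpec:
    plants: list[ContactPlant] = field(default_factory=list)


@dataclass
class LandscapePlantSpec:
    """Spec for a synthetic affinity/similarity dataset with planted cliffs."""

    n_ligands: int
    seed: int
    background_similarity: tuple[float, float] = (0.1, 0.5)
    background_affinity: tuple[float, float] = (-9.6, -5.8)
    cliffs: list[tuple[float, float]] = field(default_factory=list)  # (s, d_BA)

    def __post_init__(self) -> None:
        lo, hi = self.background_similarity
        if not (0 <= lo <= hi <= 1):
            raise ValueError("background similarity range must lie in [0,1]")
        for s, _dba in self.cliffs:
            if not (0 <= s <= 1):
                raise ValueError(f"cliff similarity {s} outside [0,1]")
        if 2 * len(self.cliffs) > self.n_ligands:
            raise ValueError("not enough ligands to host the requested cliffs")


# Spacing between independent plant units; generously larger than any
# detection cutoff so plants cannot interfere.
_PLANT_SPACING = 25.0


def _hbond_unit(plant: ContactPlant, origin: np.ndarray):
    """Ligand N-H donor to a protein backbone O acceptor.

    The acceptor O sits at the unit origin, the donor N on the +x axis
    at the planted distance; H is placed in the xy-plane so that the
    D-H...A angle equals the planted angle exactly.
    """
    d, theta = plant.distance, math.radians(plant.angle if plant.angle is not None else 180.0)
    o_pos = origin
    n_pos = origin + np.array([d, 0.0, 0.0])
    # triangle N-H-O with |NH| = 1.0: sine rule gives the angle at O
    angle_o = math.asin(min(1.0, math.sin(theta) / d))
    angle_n = math.pi - theta - angle_o
    h_pos = n_pos + np.array([-math.cos(angle_n), math.sin(angle_n), 0.0])
    protein = [
        ("O", "O", o_pos),
        ("C", "C", origin + np.array([-1.0, -0.72, 0.0])),
        ("CA", "C", origin + np.array([-2.2, 0.18, 0.0])),
    ]
    ligand = [("N1", "N", n_pos), ("H1", "H", h_pos)]
    return protein, ligand


def _halogen_unit(plant: ContactPlant, origin: np.ndarray):
    """Ligand C-Br donor to a protein backbone O acceptor (sigma-hole)."""
    d = plant.distance
    theta = math.radians(plant.angle if plant.angle is not None else 180.0)
    o_pos = origin
    x_pos = origin + np.array([d, 0.0, 0.0])
    c_pos = x_pos + 1.9 * np.array([-math.cos(theta), math.sin(theta), 0.0])
    protein = [
        ("O", "O", o_pos),
        ("C", "C", origin + np.array([-1.0, -0.72, 0.0])),
        ("CA", "C", origin + np.array([-2.2, 0.18, 0.0])),
    ]
    ligand = [("BR1", "BR", x_pos), ("C1", "C", c_pos)]
    return protein, ligand


def _hydrophobic_unit(plant: ContactPlant, origin: np.ndarray):
    """Ligand apolar carbon near a leucine side-chain carbon."""
    d = plant.distance
    protein = [
        ("CD1", "C", origin),
        ("CA", "C", origin + np.array([-2.5, 1.0, 0.0])),
    ]
    ligand = [("C1", "C", origin + np.array([d, 0.0, 0.0]))]
    return protein, ligand


_UNIT_BUILDERS = {
    "hbond": _hbond_unit,
    "halogen_bond": _halogen_unit,
    "hydrophobic": _hydrophobic_unit,
}


def synth_complex(
    spec: ComplexPlantSpec, path: str | Path | None = None
) -> tuple[ComplexStructure, str]:
    """Build a toy complex realizing each planted contact exactly.

    Every plant occupies its own residue, translated far from the
    others, so detected contacts map one-to-one onto the spec.  Returns
    the in-memory structure (full float precision; measured geometry
    matches the spec to well below 1e-6 A / 1e-4 deg) and the PDB text;
    ``path`` additionally writes the file.
    """
    protein_atoms: list[Atom] = []
    ligand_atoms: list[Atom] = []
    serial = 0

    def add(atoms_list, name, element, pos, res_name, res_seq, chain):
        nonlocal serial
        serial += 1
        atoms_list.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                res_name=res_name,
                res_seq=res_seq,
                icode="",
                chain=chain,
                x=float(pos[0]),
                y=float(pos[1]),
                z=float(pos[2]),
                b_factor=20.0,
                occupancy=1.0,
            )
        )

    for i, plant in enumerate(spec.plants):
        origin = np.array([0.0, _PLANT_SPACING * i, 0.0])
        prot, lig = _UNIT_BUILDERS[plant.kind](plant, origin)
        for name, element, pos in prot:
            add(protein_atoms, name, element, pos, plant.residue_name, 10 + i, "A")
        for name, element, pos in lig:
            # unique ligand atom names across plants
            add(ligand_atoms, f"{name[:-1]}{i + 1}" if name[-1].isdigit() else name, element, pos, "LIG", 900, "L")

    if not spec.plants:
        # an inert ligand atom far from any protein atom
        add(protein_atoms, "CA", "C", np.zeros(3), "ALA", 10, "A")
        add(ligand_atoms, "C1", "C", np.array([50.0, 50.0, 50.0]), "LIG", 900, "L")

    complex_ = ComplexStructure(
        protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms,
        ligand_selector=("LIG", "L", 900),
    )
    pdb_text = write_pdb(complex_, path)
    return complex_, pdb_text


def write_pdb(c: ComplexStructure, path: str | Path | None = None) -> str:
    """Serialize a complex as PDB text (ATOM/HETATM/TER/END)."""

    def fmt(record: str, a: Atom) -> str:
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        return (
            f"{record:<6s}{a.serial:>5d} {name:<4s}{'':1s}{a.res_name:>3s} "
            f"{a.chain:1s}{a.res_seq:>4d}{a.icode or '':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
            f"{'':10s}{a.element:>2s}"
        )

    lines = [fmt("ATOM", a) for a in c.protein_atoms]
    lines.append("TER")
    lines += [fmt("HETATM", a) for a in c.ligand_atoms]
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def synth_landscape(
    spec: LandscapePlantSpec,
) -> tuple[list[ActivityRecord], SimilarityMatrix]:
    """Synthetic affinity records and similarity matrix with planted cliffs.

    Background pair similarities and per-ligand affinities are drawn
    uniformly from the spec ranges with a seeded generator, so the
    output is reproducible.  Cliff k occupies the ligand pair
    (2k, 2k+1): its similarity is set to the planted s (which must
    exceed the background similarity ceiling) and the second member's
    affinity is offset by the planted d_BA, so the pair realizes the
    requested (s, d_BA) exactly.
    """
    bg_lo, bg_hi = spec.background_similarity
    for s, _dba in spec.cliffs:
        if s <= bg_hi:
            raise ValueError(
                f"cliff similarity {s} incompatible with background ceiling {bg_hi}: "
                "a threshold cannot separate plant from background"
            )
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ligands
    ids = [f"L{i:03d}" for i in range(n)]
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = rng.uniform(bg_lo, bg_hi)
    aff = rng.uniform(*spec.background_affinity, size=n)
    for k, (s, dba) in enumerate(spec.cliffs):
        i, j = 2 * k, 2 * k + 1
        values[i, j] = values[j, i] = s
        aff[j] = aff[i] - abs(dba)
    records = [
        ActivityRecord(ligand_id=ids[i], value=float(aff[i]), value_kind="binding_affinity")
        for i in range(n)
    ]
    return records, SimilarityMatrix(ids=ids, values=values, measure="external")


def packaged_table_checksum(table: str) -> str:
    data = resources.files("bindscape.data").joinpath(f"{table}.tsv").read_bytes()
    return hashlib.sha256(data).hexdigest()


def load_packaged_tables(table: str) -> list[EnergyRecord]:
    """Load a packaged docking-energy table: ``ck2a`` (40 rows, all four
    glycone series), ``pim1`` or ``rio1`` (10 rows each, difluoro series).
    """
    if table not in PACKAGED_TABLES:
        raise ValueError(f"unknown table {table!r}; choose from {PACKAGED_TABLES}")
    if packaged_table_checksum(table) != PACKAGED_SHA256[table]:
        raise ValueError(f"packaged table {table!r} failed its checksum pin")
    with resources.as_file(resources.files("bindscape.data").joinpath(f"{table}.tsv")) as p:
        records = ingest_energy_table(p, sep="\t")
    forced = _TABLE_SERIES[table]
    if forced is not None:
        for r in records:
            r.series = forced
            from bindscape.ligands import LABEL_TO_PATTERN, ligand_id

            pattern = LABEL_TO_PATTERN.get(r.ligand_label)
            if pattern is not None:
                r.ligand_id = ligand_id(pattern, forced)
    return records
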