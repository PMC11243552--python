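"""Geometric detection of noncovalent protein-ligand interactions.

Detects hydrogen bonds, halogen bonds and hydrophobic contacts in a 3D
complex using distance/angle criteria, and converts contact lists into
sparse binding fingerprints (per-residue or per-ligand-atom).

The default criteria are deliberately permissive enough to capture the
interactions typically reported for halogenated benzimidazole / kinase
co-crystals: a strong hydrogen bond at D...A <= 3.6 A and D-H...A >= 120
deg, a weak envelope up to 4.1 A / 90 deg (covering long N-H...Cl and
highly non-linear O-H...O bonds), halogen bonds at X...A <= 3.8 A with a
near-linear C-X...A sigma-hole angle >= 140 deg, and apolar C...C
hydrophobic contacts up to 4.0 A.  All cutoffs are keyword arguments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from bindscape.binding_mode import BindingFingerprint

__all__ = [
    "Atom",
    "ComplexStructure",
    "ContactRecord",
    "load_complex",
    "detect_hbonds",
    "detect_halogen_bonds",
    "detect_hydrophobic",
    "detect_all_contacts",
    "measure_geometry",
    "contacts_to_fingerprint",
    "contacts_to_tsv",
    "contacts_to_json",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class Atom(NamedTuple):
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    icode: str
    chain: str
    x: float
    y: float
    z: float
    b_factor: float
    occupancy: float

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def residue_key(self) -> str:
        return f"{self.res_name}{self.res_seq}{self.icode.strip()}"


@dataclass
class ComplexStructure:
    """A protein plus one selected hetero (ligand) group."""

    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]
    ligand_selector: tuple[str, str | None, int | None]

    def __post_init__(self) -> None:
        for a in self.protein_atoms + self.ligand_atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates on atom serial {a.serial}")
        if not self.ligand_atoms:
            raise ValueError("ligand_atoms is empty after selection")


@dataclass
class ContactRecord:
    """One detected noncovalent interaction with its geometry."""

    kind: str  # hbond | halogen_bond | hydrophobic
    ligand_atom: Atom
    partner_atom: Atom
    residue: tuple[str, int, str]  # (name, number, chain)
    distance: float
    angle: float | None
    strength_class: str  # strong | weak

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be > 0")
        if self.angle is not None and not (0 <= self.angle <= 180):
            raise ValueError("contact angle must lie in [0,180]")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def load_complex(
    path: str | Path,
    ligand_selector: str | tuple,
    keep_waters: bool = False,
) -> ComplexStructure:
    """Read a PDB file and select exactly one hetero group as the ligand.

    ``ligand_selector`` is ``resname`` or ``(resname, chain, resseq)``
    (chain/resseq may be None to match any).  Waters are excluded by
    default; alternate locations are resolved to the highest occupancy.
    """
    if isinstance(ligand_selector, str):
        ligand_selector = (ligand_selector, None, None)
    sel_name, sel_chain, sel_seq = (list(ligand_selector) + [None, None])[:3]

    st = gemmi.read_structure(str(path))
    model = st[0]

    protein: list[Atom] = []
    het_groups: dict[tuple[str, str, int, str], list[Atom]] = {}
    for chain in model:
        for res in chain:
            is_water = res.name in WATER_NAMES or res.is_water()
            if is_water and not keep_waters:
                continue  # retained waters join the protein side (bridge partners)
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=name,
                        element=ga.element.name.upper(),
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        chain=chain.name,
                        x=ga.pos.x,
                        y=ga.pos.y,
                        z=ga.pos.z,
                        b_factor=ga.b_iso,
                        occupancy=ga.occ,
                    )
                )
            if is_water:
                protein.extend(atoms)
            elif res.het_flag == "H":
                het_groups[(res.name, chain.name, res.seqid.num, res.seqid.icode or "")] = atoms
            else:
                protein.extend(atoms)

    matches = [
        key
        for key in het_groups
        if key[0] == sel_name
        and (sel_chain is None or key[1] == sel_chain)
        and (sel_seq is None or key[2] == sel_seq)
    ]
    if sel_name in WATER_NAMES:
        raise ValueError(f"selector {sel_name!r} names a water; waters are excluded")
    if len(matches) != 1:
        candidates = sorted(f"{n}/{c}/{s}" for n, c, s, _ in het_groups)
        raise ValueError(
            f"ligand selector {ligand_selector!r} matched {len(matches)} hetero groups; "
            f"candidates: {candidates}"
        )
    return ComplexStructure(
        protein_atoms=protein,
        ligand_atoms=het_groups[matches[0]],
        ligand_selector=(sel_name, sel_chain, sel_seq),
    )


# ---------------------------------------------------------------------------
# typing tables

# Protein donor heavy atoms -> antecedent used for the heavy-atom
# surrogate angle when no hydrogens are present.
PROTEIN_DONORS: dict[tuple[str, str], str] = {}
for _res in (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE SER THR TRP TYR VAL".split()
):
    PROTEIN_DONORS[(_res, "N")] = "CA"  # backbone amide (PRO excluded)
for _res, _pairs in {
    "SER": [("OG", "CB")],
    "THR": [("OG1", "CB")],
    "TYR": [("OH", "CZ")],
    "ASN": [("ND2", "CG")],
    "GLN": [("NE2", "CD")],
    "LYS": [("NZ", "CE")],
    "ARG": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "HIS": [("ND1", "CG"), ("NE2", "CD2")],
    "TRP": [("NE1", "CD1")],
    "CYS": [("SG", "CB")],
}.items():
    for _atom, _ante in _pairs:
        PROTEIN_DONORS[(_res, _atom)] = _ante

PROTEIN_ACCEPTOR_ATOMS = {"O", "OXT"}
PROTEIN_SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
    "CYS": {"SG"},
}

HALOGENS = {"CL", "BR", "I"}
# halogens (incl. F) can act as weak hydrogen-bond acceptors
ACCEPTOR_ELEMENTS = {"N", "O", "S"}
_H_BOND_MAX = 1.25  # covalent D-H detection
_HEAVY_BOND_MAX = 1.85  # generic heavy-atom covalent bond
_C_X_BOND_MAX = {"CL": 2.1, "BR": 2.3, "I": 2.5}


def _neighbors_within(atoms: Sequence[Atom], center: Atom, cutoff: float) -> list[Atom]:
    c = center.pos
    return [
        a
        for a in atoms
        if a.serial != center.serial and np.linalg.norm(a.pos - c) <= cutoff
    ]


def _angle(a: np.ndarray, apex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - apex, b - apex
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _protein_residue(atom: Atom) -> tuple[str, int, str]:
    return (atom.res_name, atom.res_seq, atom.chain)


def _donor_sites(
    atoms: Sequence[Atom],
    is_protein: bool,
    infer_missing_h: bool,
) -> list[tuple[Atom, list[Atom], Atom | None]]:
    """(donor, explicit hydrogens, surrogate antecedent) triples."""
    hydrogens = [a for a in atoms if a.element == "H"]
    sites = []
    for a in atoms:
        if a.element not in {"N", "O", "S"}:
            continue
        hs = _neighbors_within(hydrogens, a, _H_BOND_MAX)
        if hs:
            sites.append((a, hs, None))
            continue
        if is_protein:
            ante_name = PROTEIN_DONORS.get((a.res_name, a.name))
            if ante_name is None:
                continue
            ante = next(
                (
                    p
                    for p in atoms
                    if p.chain == a.chain
                    and p.res_seq == a.res_seq
                    and p.name == ante_name
                ),
                None,
            )
            if ante is not None:
                sites.append((a, [], ante))
        elif infer_missing_h:
            heavies = [n for n in _neighbors_within(atoms, a, _HEAVY_BOND_MAX) if n.element != "H"]
            if heavies:
                ante = min(heavies, key=lambda n: np.linalg.norm(n.pos - a.pos))
                sites.append((a, [], ante))
    return sites


def _acceptor_sites(atoms: Sequence[Atom], is_protein: bool) -> list[Atom]:
    out = []
    for a in atoms:
        if is_protein:
            if a.name in PROTEIN_ACCEPTOR_ATOMS and a.element == "O":
                out.append(a)
            elif a.name in PROTEIN_SIDECHAIN_ACCEPTORS.get(a.res_name, set()):
                out.append(a)
        else:
            if a.element in ACCEPTOR_ELEMENTS or a.element in HALOGENS or a.element == "F":
                out.append(a)
    return out


def _hbond_angle(donor: Atom, hydrogens: list[Atom], ante: Atom | None, acceptor: Atom) -> float:
    if hydrogens:
        # D-H...A angle at the hydrogen; best (most linear) hydrogen counts
        return max(_angle(donor.pos, h.pos, acceptor.pos) for h in hydrogens)
    assert ante is not None
    # heavy-atom surrogate: antecedent-D...A angle at the donor
    return _angle(ante.pos, donor.pos, acceptor.pos)


def detect_hbonds(
    c: ComplexStructure,
    d_max: float = 3.6,
    d_max_weak: float = 4.1,
    angle_min: float = 120.0,
    angle_min_weak: float = 90.0,
    infer_missing_h: bool = True,
) -> list[ContactRecord]:
    """Hydrogen bonds between ligand and protein, both directions.

    Distance is donor-heavy to acceptor-heavy.  Contacts within
    ``d_max``/``angle_min`` are classed strong; those only within the
    weak envelope (``d_max_weak``/``angle_min_weak``) are classed weak.
    Without explicit hydrogens the angle falls back to the heavy-atom
    surrogate (antecedent-donor-acceptor); if the ligand has neither
    hydrogens nor inference enabled, an error is raised.
    """
    lig_has_h = any(a.element == "H" for a in c.ligand_atoms)
    lig_has_don_candidates = any(a.element in {"N", "O", "S"} for a in c.ligand_atoms)
    if not lig_has_h and lig_has_don_candidates and not infer_missing_h:
        raise ValueError(
            "ligand has no hydrogens; enable infer_missing_h=True to use the "
            "heavy-atom surrogate angle"
        )

    records: list[ContactRecord] = []
    directions = [
        (_donor_sites(c.ligand_atoms, False, infer_missing_h), _acceptor_sites(c.protein_atoms, True), True),
        (_donor_sites(c.protein_atoms, True, infer_missing_h), _acceptor_sites(c.ligand_atoms, False), False),
    ]
    for donors, acceptors, ligand_is_donor in directions:
        if not donors or not acceptors:
            continue
        tree = cKDTree([a.pos for a in acceptors])
        for donor, hs, ante in donors:
            for j in tree.query_ball_point(donor.pos, d_max_weak):
                acc = acceptors[j]
                d = float(np.linalg.norm(acc.pos - donor.pos))
                if d < 1e-9:
                    continue
                theta = _hbond_angle(donor, hs, ante, acc)
                if d <= d_max and theta >= angle_min:
                    klass = "strong"
                elif theta >= angle_min_weak:
                    klass = "weak"
                else:
                    continue
                lig_atom, prot_atom = (donor, acc) if ligand_is_donor else (acc, donor)
                records.append(
                    ContactRecord(
                        kind="hbond",
                        ligand_atom=lig_atom,
                        partner_atom=prot_atom,
                        residue=_protein_residue(prot_atom),
                        distance=d,
                        angle=theta,
                        strength_class=klass,
                    )
                )
    records.sort(key=lambda r: r.distance)
    return records


def detect_halogen_bonds(
    c: ComplexStructure, d_max: float = 3.8, angle_min: float = 140.0
) -> list[ContactRecord]:
    """Halogen bonds: ligand C-X (X in Cl/Br/I) to protein O/N/S acceptors.

    Records the X...A distance and the sigma-hole C-X...A angle.
    Fluorine is excluded (no appreciable sigma-hole).  Returns an empty
    list when the ligand carries no suitable halogens.
    """
    acceptors = [a for a in c.protein_atoms if a.element in ACCEPTOR_ELEMENTS]
    records: list[ContactRecord] = []
    if not acceptors:
        return records
    tree = cKDTree([a.pos for a in acceptors])
    for x in c.ligand_atoms:
        if x.element not in HALOGENS:
            continue
        bond_max = _C_X_BOND_MAX[x.element]
        carbons = [
            a
            for a in _neighbors_within(c.ligand_atoms, x, bond_max)
            if a.element == "C"
        ]
        if not carbons:
            continue
        carbon = min(carbons, key=lambda a: np.linalg.norm(a.pos - x.pos))
        for j in tree.query_ball_point(x.pos, d_max):
            acc = acceptors[j]
            d = float(np.linalg.norm(acc.pos - x.pos))
            theta = _angle(carbon.pos, x.pos, acc.pos)
            if theta < angle_min:
                continue
            records.append(
                ContactRecord(
                    kind="halogen_bond",
                    ligand_atom=x,
                    partner_atom=acc,
                    residue=_protein_residue(acc),
                    distance=d,
                    angle=theta,
                    strength_class="strong",
                )
            )
    records.sort(key=lambda r: r.distance)
    return records


def _apolar_carbons(atoms: Sequence[Atom]) -> list[Atom]:
    heteros = [a for a in atoms if a.element in {"N", "O", "S"}]
    out = []
    for a in atoms:
        if a.element != "C":
            continue
        if any(np.linalg.norm(h.pos - a.pos) <= _HEAVY_BOND_MAX for h in heteros):
            continue  # polarized carbon (bonded to N/O/S)
        out.append(a)
    return out


def detect_hydrophobic(c: ComplexStructure, d_max: float = 4.0) -> list[ContactRecord]:
    """Apolar-carbon to apolar-carbon contacts within ``d_max``.

    Aggregated to one record per (ligand atom, residue) at the minimum
    observed distance.
    """
    lig_c = _apolar_carbons(c.ligand_atoms)
    prot_c = _apolar_carbons(c.protein_atoms)
    if not lig_c or not prot_c:
        return []
    tree = cKDTree([a.pos for a in prot_c])
    best: dict[tuple[int, tuple[str, int, str]], tuple[float, Atom, Atom]] = {}
    for la in lig_c:
        for j in tree.query_ball_point(la.pos, d_max):
            pa = prot_c[j]
            d = float(np.linalg.norm(pa.pos - la.pos))
            key = (la.serial, _protein_residue(pa))
            if key not in best or d < best[key][0]:
                best[key] = (d, la, pa)
    records = [
        ContactRecord(
            kind="hydrophobic",
            ligand_atom=la,
            partner_atom=pa,
            residue=res,
            distance=d,
            angle=None,
            strength_class="strong",
        )
        for (serial, res), (d, la, pa) in best.items()
    ]
    records.sort(key=lambda r: r.distance)
    return records


def detect_all_contacts(c: ComplexStructure, **kwargs) -> list[ContactRecord]:
    """Run all three detectors; kwargs are routed by prefix-free names."""
    hb = {k: v for k, v in kwargs.items() if k in {"d_max", "d_max_weak", "angle_min", "angle_min_weak", "infer_missing_h"}}
    return (
        detect_hbonds(c, **hb)
        + detect_halogen_bonds(c)
        + detect_hydrophobic(c)
    )


def _find_atom(c: ComplexStructure, ref) -> Atom:
    if isinstance(ref, Atom):
        return ref
    pool = c.ligand_atoms + c.protein_atoms
    if isinstance(ref, int):
        for a in pool:
            if a.serial == ref:
                return a
        raise KeyError(f"no atom with serial {ref}")
    chain, res_seq, name = ref
    for a in pool:
        if a.chain == chain and a.res_seq == res_seq and a.name == name:
            return a
    raise KeyError(f"no atom matching (chain={chain!r}, res_seq={res_seq}, name={name!r})")


def measure_geometry(
    c: ComplexStructure, atom_ref_a, atom_ref_b, atom_ref_c=None
) -> tuple[float, float | None]:
    """Euclidean distance a-b and, when c is given, the angle a-b-c (apex b).

    Pure geometry; independent of any detection criterion.  Atom
    references are serial numbers, ``(chain, res_seq, atom_name)``
    tuples, or :class:`Atom` objects.
    """
    a = _find_atom(c, atom_ref_a)
    b = _find_atom(c, atom_ref_b)
    d = float(np.linalg.norm(a.pos - b.pos))
    ang = None
    if atom_ref_c is not None:
        cc = _find_atom(c, atom_ref_c)
        ang = _angle(a.pos, b.pos, cc.pos)
    return d, ang


def contacts_to_fingerprint(
    contacts: Sequence[ContactRecord],
    perspective: str = "residue",
    weighting: str = "count",
    ligand_id: str = "",
) -> BindingFingerprint:
    """Aggregate contacts into a sparse binding fingerprint.

    ``perspective='residue'`` keys by residue (name+number),
    ``'ligand_atom'`` by ligand atom name.  ``weighting='count'`` sums
    contact counts; ``'distance_weight'`` sums 1/d per contact.
    """
    if perspective not in {"residue", "ligand_atom"}:
        raise ValueError(f"unknown perspective {perspective!r}")
    if weighting not in {"count", "distance_weight"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    entries: dict[str, float] = {}
    for rec in contacts:
        if perspective == "residue":
            name, num, _chain = rec.residue
            key = f"{name}{num}"
        else:
            key = rec.ligand_atom.name
        w = 1.0 if weighting == "count" else 1.0 / rec.distance
        entries[key] = entries.get(key, 0.0) + w
    return BindingFingerprint(ligand_id=ligand_id, entries=entries, source="contacts")


def contacts_to_tsv(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tligand_atom\tresidue\tdistance\tangle\tclass\n")
        for r in contacts:
            res = f"{r.residue[0]}{r.residue[1]}/{r.residue[2]}"
            ang = "" if r.angle is None else f"{r.angle:.2f}"
            fh.write(
                f"{r.kind}\t{r.ligand_atom.name}\t{res}\t{r.distance:.3f}\t{ang}\t{r.strength_class}\n"
            )


def contacts_to_json(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    payload = [
        {
            "kind": r.kind,
            "ligand_atom": r.ligand_atom.name,
            "partner_atom": r.partner_atom.name,
            "residue": {"name": r.residue[0], "number": r.residue[1], "chain": r.residue[2]},
            "distance": r.distance,
            "angle": r.angle,
            "class": r.strength_class,
        }
        for r in contacts
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
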