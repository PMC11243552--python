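"""The designed ligand library and molecular similarity measures.

The library crosses ten halogenation patterns of the benzimidazole ring
(positions 4-7, i.e. R1-R4) with four glycone options at N(1): no sugar,
ribose, 2'-deoxyribose and 2'-deoxy-2',2'-difluoro-ribose.  Similarity
between ligands is computed either from circular (Morgan) fingerprints or
from a binned pharmacophore feature-pair descriptor; externally computed
similarity matrices can be loaded from CSV so that other descriptors can
be plugged into the landscape analysis unchanged.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Series",
    "Ligand",
    "Fingerprint",
    "SimilarityMatrix",
    "HALOGEN_PATTERNS",
    "PATTERN_LABELS",
    "enumerate_designed_ligands",
    "parse_ligands",
    "circular_fingerprint",
    "feature_pair_descriptor",
    "tanimoto",
    "similarity_matrix",
    "read_similarity_csv",
    "write_similarity_csv",
]


class Series(str, enum.Enum):
    """Glycone attached at N(1) of the benzimidazole ring."""

    NONE = "none"
    RIBOSE = "ribose"
    DEOXYRIBOSE = "deoxyribose"
    DIFLUORO = "difluoro"


@dataclass
class Ligand:
    """One library member: halogenation pattern plus glycone series.

    ``substituents`` maps the ring positions R1-R4 (benzimidazole C4-C7)
    to an element symbol in {H, F, Cl, Br, I}.  ``structure`` is an
    optional SMILES string; ``conformer`` an optional list of
    ``(element, x, y, z)`` tuples in angstroms.
    """

    id: str
    series: Series
    substituents: dict[str, str]
    structure: str | None = None
    conformer: list[tuple[str, float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ligand id must be nonempty")
        if set(self.substituents) != {"R1", "R2", "R3", "R4"}:
            raise ValueError(
                "substituent positions must be exactly {R1,R2,R3,R4}, "
                f"got {sorted(self.substituents)}"
            )
        if self.conformer is not None and len(self.conformer) == 0:
            raise ValueError("conformer, when present, must contain >= 1 atom")


@dataclass
class Fingerprint:
    """Folded binary fingerprint with optional per-bit counts."""

    bits: frozenset[int]
    n_bits: int
    counts: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        bad = [b for b in self.bits if not (0 <= b < self.n_bits)]
        if bad:
            raise ValueError(f"bit indices out of range [0,{self.n_bits}): {bad}")


@dataclass
class SimilarityMatrix:
    """Symmetric ligand-by-ligand similarity matrix with entries in [0,1]."""

    ids: list[str]
    values: np.ndarray
    measure: str = "circular"  # circular | feature_pair | external

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("similarity matrix must have unit diagonal")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("similarities must lie in [0,1]")

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])


# Halogenation patterns: pattern key -> {R1: C4, R2: C5, R3: C6, R4: C7}.
HALOGEN_PATTERNS: dict[str, dict[str, str]] = {
    "4567-tetraBr": {"R1": "Br", "R2": "Br", "R3": "Br", "R4": "Br"},
    "4567-tetraCl": {"R1": "Cl", "R2": "Cl", "R3": "Cl", "R4": "Cl"},
    "4567-tetraI": {"R1": "I", "R2": "I", "R3": "I", "R4": "I"},
    "56-diBr": {"R1": "H", "R2": "Br", "R3": "Br", "R4": "H"},
    "56-diCl": {"R1": "H", "R2": "Cl", "R3": "Cl", "R4": "H"},
    "56-diI": {"R1": "H", "R2": "I", "R3": "I", "R4": "H"},
    "56-diBr-47-diCl": {"R1": "Cl", "R2": "Br", "R3": "Br", "R4": "Cl"},
    "56-diBr-47-diI": {"R1": "I", "R2": "Br", "R3": "Br", "R4": "I"},
    "56-diI-47-diBr": {"R1": "Br", "R2": "I", "R3": "I", "R4": "Br"},
    "56-diI-47-diCl": {"R1": "Cl", "R2": "I", "R3": "I", "R4": "Cl"},
}

# Human-readable labels as used in docking-energy tables.
PATTERN_LABELS: dict[str, str] = {
    "4567-tetraBr": "4,5,6,7-tetrabromo-",
    "4567-tetraCl": "4,5,6,7-tetrachloro-",
    "4567-tetraI": "4,5,6,7-tetraiodo-",
    "56-diBr": "5,6-dibromo-",
    "56-diCl": "5,6-dichloro-",
    "56-diI": "5,6-diiodo-",
    "56-diBr-47-diCl": "5,6-dibromo,4,7-dichloro-",
    "56-diBr-47-diI": "5,6-dibromo,4,7-diiodo-",
    "56-diI-47-diBr": "5,6-diiodo,4,7-dibromo-",
    "56-diI-47-diCl": "5,6-diiodo,4,7-dichloro-",
}

LABEL_TO_PATTERN: dict[str, str] = {v: k for k, v in PATTERN_LABELS.items()}

_GLYCONE_SMILES: dict[Series, str | None] = {
    Series.NONE: None,
    Series.RIBOSE: "C3OC(CO)C(O)C3O",
    Series.DEOXYRIBOSE: "C3OC(CO)C(O)C3",
    Series.DIFLUORO: "C3OC(CO)C(O)C3(F)F",
}


def _benzimidazole_smiles(subs: Mapping[str, str], series: Series) -> str:
    """SMILES for a (possibly N1-glycosylated) 4-7 substituted benzimidazole."""

    def grp(pos: str) -> str:
        el = subs[pos]
        return "" if el == "H" else f"({el})"

    r1 = subs["R1"] if subs["R1"] != "H" else ""
    gly = _GLYCONE_SMILES[series]
    n1 = f"n({gly})" if gly else "[nH]"
    return f"{r1}c1c{grp('R2')}c{grp('R3')}c{grp('R4')}c2{n1}cnc12"


def ligand_id(pattern: str, series: Series | str) -> str:
    """Canonical ligand id ``<halogen-pattern>_<series>``."""
    return f"{pattern}_{Series(series).value}"


def enumerate_designed_ligands() -> list[Ligand]:
    """Enumerate the full designed library: 10 halogenation patterns x 4 series.

    Deterministic: ids and order are identical across runs (series-major,
    patterns in the canonical table order).
    """
    out: list[Ligand] = []
    for series in Series:
        for pattern, subs in HALOGEN_PATTERNS.items():
            out.append(
                Ligand(
                    id=ligand_id(pattern, series),
                    series=series,
                    substituents=dict(subs),
                    structure=_benzimidazole_smiles(subs, series),
                )
            )
    return out


def _ligand_from_mol(mol: Chem.Mol, fallback_id: str) -> Ligand:
    name = (mol.GetProp("_Name") if mol.HasProp("_Name") else "") or fallback_id
    conformer = None
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        if conf.Is3D():
            conformer = [
                (a.GetSymbol(), *map(float, conf.GetAtomPosition(a.GetIdx())))
                for a in mol.GetAtoms()
            ]
    return Ligand(
        id=name,
        series=Series.NONE,
        substituents={"R1": "H", "R2": "H", "R3": "H", "R4": "H"},
        structure=Chem.MolToSmiles(Chem.RemoveHs(mol)),
        conformer=conformer,
    )


def parse_ligands(path: str | Path) -> list[Ligand]:
    """Read ligands from a SMILES-lines file or an SDF (by extension).

    SMILES files hold one record per line, optionally tab-separated
    ``SMILES<TAB>id``.  An unreadable record raises :class:`ValueError`
    naming the 1-based record index; an empty file returns an empty list
    with a warning.
    """
    path = Path(path)
    mols: list[Ligand] = []
    if path.suffix.lower() in {".sdf", ".mol", ".sd"}:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                raise ValueError(f"unreadable record {i} in {path.name}")
            mols.append(_ligand_from_mol(mol, fallback_id=f"{path.stem}_{i}"))
    else:
        with open(path) as fh:
            lines = [ln.strip() for ln in fh]
        records = [(i, ln) for i, ln in enumerate(lines, start=1) if ln]
        for rec_no, (i, ln) in enumerate(records, start=1):
            parts = ln.split("\t")
            smiles = parts[0].strip()
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ValueError(f"unreadable record {rec_no} (line {i}) in {path.name}")
            name = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{rec_no}"
            mol.SetProp("_Name", name)
            mols.append(_ligand_from_mol(mol, fallback_id=name))
    if not mols:
        warnings.warn(f"{path.name}: no ligand records found", stacklevel=2)
    return mols


def _mol_from_ligand(ligand: Ligand) -> Chem.Mol:
    if not ligand.structure:
        raise ValueError(f"ligand {ligand.id!r} has no structure")
    mol = Chem.MolFromSmiles(ligand.structure)
    if mol is None:
        raise ValueError(f"ligand {ligand.id!r}: unparseable structure {ligand.structure!r}")
    return mol


def circular_fingerprint(ligand: Ligand, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Morgan (circular) fingerprint of the ligand structure.

    Deterministic: identical structures give identical fingerprints.  This
    is the toolkit's open substitute for fragment-sphere similarity
    descriptors: both count matched circular atom environments.
    """
    mol = _mol_from_ligand(ligand)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    cfp = gen.GetCountFingerprint(mol)
    counts = {int(k): int(v) for k, v in cfp.GetNonzeroElements().items()}
    return Fingerprint(bits=frozenset(counts), n_bits=n_bits, counts=counts)


# Pharmacophore feature typing (pragmatic SMARTS; an atom may carry
# several features, as usual in feature-pair descriptors).
_FEATURE_SMARTS = {
    "donor": "[$([N;!H0;v3,v4&+1]),$([O,S;H1;+0])]",
    "acceptor": (
        "[$([O,S;H1;v2;!$(*-*=[O,N,P,S])]),$([O,S;H0;v2]),$([O,S;-]),"
        "$([N;v3;!$(N-*=[O,N,P,S])]),$([nH0,o,s;+0])]"
    ),
    "hydrophobic": "[C,c;!$([C,c]~[N,n,O,o,F])]",
    "halogen": "[F,Cl,Br,I]",
}
_FEATURE_TYPES = ("donor", "acceptor", "aromatic", "hydrophobic", "halogen")
_PAIR_INDEX = {
    pair: k
    for k, pair in enumerate(
        (a, b)
        for i, a in enumerate(_FEATURE_TYPES)
        for b in _FEATURE_TYPES[i:]
    )
}
FEATURE_PAIR_BIN_WIDTH = 2.0  # angstrom
FEATURE_PAIR_MAX_DIST = 12.0
_N_BINS = int(FEATURE_PAIR_MAX_DIST / FEATURE_PAIR_BIN_WIDTH)
FEATURE_PAIR_N_BITS = len(_PAIR_INDEX) * _N_BINS
# Approximate through-bond distance per bond for the topological fallback.
_BOND_LENGTH = 1.5


def _find_features(mol: Chem.Mol) -> list[tuple[str, tuple[int, ...]]]:
    feats: list[tuple[str, tuple[int, ...]]] = []
    for kind, smarts in _FEATURE_SMARTS.items():
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            feats.append((kind, (match[0],)))
    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            feats.append(("aromatic", tuple(ring)))
    return feats


def feature_pair_descriptor(ligand: Ligand) -> Fingerprint:
    """Binned pharmacophore feature-pair descriptor.

    Encodes every unordered pair of pharmacophore features (donor,
    acceptor, aromatic ring, hydrophobic carbon, halogen) together with
    the inter-feature distance folded into 2 angstrom bins from 0 to 12.
    With a conformer present, distances are Euclidean (aromatic features
    sit at the ring centroid); otherwise the topological shortest path
    scaled by a mean bond length of 1.5 angstrom is used.
    """
    mol = _mol_from_ligand(ligand)
    feats = _find_features(mol)
    if not feats:
        warnings.warn(f"ligand {ligand.id!r}: no pharmacophore features detected", stacklevel=2)
        return Fingerprint(bits=frozenset(), n_bits=FEATURE_PAIR_N_BITS, counts={})

    coords: np.ndarray | None = None
    if ligand.conformer is not None and len(ligand.conformer) >= mol.GetNumAtoms():
        coords = np.array([[x, y, z] for _, x, y, z in ligand.conformer[: mol.GetNumAtoms()]])
    topo = None if coords is not None else Chem.GetDistanceMatrix(mol)

    def feat_pos(atoms: tuple[int, ...]) -> np.ndarray:
        return coords[list(atoms)].mean(axis=0)

    counts: dict[int, int] = {}
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            (ka, aa), (kb, ab) = feats[i], feats[j]
            if aa == ab and len(aa) == 1:
                continue  # same atom carrying two feature types
            if coords is not None:
                d = float(np.linalg.norm(feat_pos(aa) - feat_pos(ab)))
            else:
                # representative atoms for the topological fallback
                d = float(topo[aa[0], ab[0]]) * _BOND_LENGTH
            if d >= FEATURE_PAIR_MAX_DIST:
                continue
            pair = tuple(sorted((ka, kb), key=_FEATURE_TYPES.index))
            bit = _PAIR_INDEX[pair] * _N_BINS + int(d / FEATURE_PAIR_BIN_WIDTH)
            counts[bit] = counts.get(bit, 0) + 1
    return Fingerprint(bits=frozenset(counts), n_bits=FEATURE_PAIR_N_BITS, counts=counts)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A .and. B| / |A .or. B| on fingerprint bit sets."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint sizes differ: {a.n_bits} != {b.n_bits}")
    if not a.bits and not b.bits:
        warnings.warn("tanimoto of two empty fingerprints: defined as 1.0", stacklevel=2)
        return 1.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


_FP_FUNCS = {
    "circular": circular_fingerprint,
    "feature_pair": feature_pair_descriptor,
}


def similarity_matrix(
    ligands: Sequence[Ligand], measure: str = "circular", **fp_kwargs
) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity matrix over a ligand list."""
    if len(ligands) < 2:
        raise ValueError("need at least 2 ligands")
    ids = [lg.id for lg in ligands]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ligand ids: {dupes}")
    if measure not in _FP_FUNCS:
        raise ValueError(f"unknown measure {measure!r}; use 'external' via read_similarity_csv")
    fps = [_FP_FUNCS[measure](lg, **fp_kwargs) for lg in ligands]
    n = len(fps)
    values = np.eye(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-empty pairs are legitimate here
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = tanimoto(fps[i], fps[j])
    return SimilarityMatrix(ids=ids, values=values, measure=measure)


def read_similarity_csv(path: str | Path) -> SimilarityMatrix:
    """Load an externally computed similarity matrix (ids as header row/column)."""
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    if list(map(str, df.index)) != ids:
        raise ValueError("similarity CSV row ids must match column ids in order")
    return SimilarityMatrix(ids=ids, values=df.to_numpy(dtype=float), measure="external")


def write_similarity_csv(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(path)
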