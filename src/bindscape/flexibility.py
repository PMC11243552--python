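"""Per-residue flexibility profiles and difference maps.

Crystallographic B-factors (atomic displacement parameters, A^2) and
simulation-derived RMSF values (A) are both carried as residue-indexed
profiles.  Profiles from different structures are made comparable by
per-chain z-scoring ("normalized B-factors"); the difference of two
normalized profiles on their shared residues highlights regions that
rigidify or loosen between complexes, and stacking such differences for
several complexes against one reference yields a diverging heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from bindscape.binding_mode import HeatmapMatrix
from bindscape.interactions import ComplexStructure

__all__ = [
    "FlexProfile",
    "extract_bfactors",
    "normalize_profile",
    "delta_profile",
    "flex_heatmap",
    "read_rmsf_csv",
    "profile_to_csv",
]


@dataclass
class FlexProfile:
    """Residue-indexed flexibility values for one structure.

    ``residues`` is an ordered list of ``(chain, residue_number, value)``;
    units are A^2 for ``kind='bfactor'`` and A for ``kind='rmsf'``
    (dimensionless once normalized).
    """

    structure_id: str
    kind: str  # bfactor | rmsf
    residues: list[tuple[str, int, float]]
    normalized: bool = False

    def __post_init__(self) -> None:
        seen = set()
        for chain, num, value in self.residues:
            if not np.isfinite(value):
                raise ValueError(f"non-finite value at {chain}/{num}")
            if (chain, num) in seen:
                raise ValueError(f"duplicate residue key {chain}/{num}")
            seen.add((chain, num))

    @property
    def units(self) -> str:
        if self.normalized:
            return "z"
        return "A^2" if self.kind == "bfactor" else "A"

    def as_dict(self) -> dict[tuple[str, int], float]:
        return {(c, n): v for c, n, v in self.residues}


def extract_bfactors(
    c: ComplexStructure, structure_id: str = "", per: str = "residue_mean"
) -> FlexProfile:
    """B-factor profile from a complex, one value per protein residue.

    ``per='residue_mean'`` averages over the residue's atoms;
    ``per='calpha'`` takes the CA atom value (residues without CA are
    skipped with a warning).
    """
    import warnings

    if per not in {"residue_mean", "calpha"}:
        raise ValueError(f"unknown per={per!r}")
    if not c.protein_atoms:
        raise ValueError("no protein atoms present")
    groups: dict[tuple[str, int], list] = {}
    order: list[tuple[str, int]] = []
    for a in c.protein_atoms:
        key = (a.chain, a.res_seq)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    residues: list[tuple[str, int, float]] = []
    for key in order:
        atoms = groups[key]
        if per == "residue_mean":
            value = float(np.mean([a.b_factor for a in atoms]))
        else:
            ca = next((a for a in atoms if a.name == "CA"), None)
            if ca is None:
                warnings.warn(f"residue {key[0]}/{key[1]} has no CA; skipped", stacklevel=2)
                continue
            value = float(ca.b_factor)
        residues.append((key[0], key[1], value))
    if not residues:
        raise ValueError("no residues with usable values")
    return FlexProfile(structure_id=structure_id, kind="bfactor", residues=residues)


def normalize_profile(p: FlexProfile) -> FlexProfile:
    """Per-chain z-score (population standard deviation).

    The output has mean 0 and stdev 1 within each chain; idempotent on
    already-normalized data.  A chain with < 2 residues or zero spread
    raises an error ("constant profile").
    """
    chains: dict[str, list[float]] = {}
    for chain, _num, value in p.residues:
        chains.setdefault(chain, []).append(value)
    stats = {}
    for chain, vals in chains.items():
        if len(vals) < 2:
            raise ValueError(f"chain {chain!r}: need >= 2 residues to normalize")
        mu = float(np.mean(vals))
        sigma = float(np.std(vals))  # population stdev
        if sigma == 0.0:
            raise ValueError(f"chain {chain!r}: constant profile, cannot normalize")
        stats[chain] = (mu, sigma)
    residues = [
        (chain, num, (value - stats[chain][0]) / stats[chain][1])
        for chain, num, value in p.residues
    ]
    return FlexProfile(
        structure_id=p.structure_id, kind=p.kind, residues=residues, normalized=True
    )


def delta_profile(p: FlexProfile, ref: FlexProfile) -> FlexProfile:
    """Difference p - ref on the shared (chain, residue_number) support.

    Reported as the raw signed difference; the sign convention (more
    rigid vs more flexible) follows from the input kind.
    """
    ref_map = ref.as_dict()
    residues = [
        (chain, num, value - ref_map[(chain, num)])
        for chain, num, value in p.residues
        if (chain, num) in ref_map
    ]
    if not residues:
        raise ValueError(
            f"profiles {p.structure_id!r} and {ref.structure_id!r} share no residues"
        )
    return FlexProfile(
        structure_id=f"{p.structure_id}-{ref.structure_id}",
        kind=p.kind,
        residues=residues,
        normalized=p.normalized and ref.normalized,
    )


def flex_heatmap(profiles: Sequence[FlexProfile], ref: FlexProfile) -> HeatmapMatrix:
    """Difference map: rows are structures, columns shared residues.

    Each row is ``delta_profile(profile, ref)`` restricted to the
    residues common to the reference and *all* profiles, so the matrix
    is rectangular.  Rendered with a red-blue diverging scheme.
    """
    if not profiles:
        raise ValueError("no profiles given")
    common = set(ref.as_dict())
    for p in profiles:
        common &= set(p.as_dict())
    if not common:
        raise ValueError("profiles share no residues with the reference")
    keys = sorted(common)
    rows = []
    for p in profiles:
        delta = delta_profile(p, ref).as_dict()
        rows.append([delta[k] for k in keys])
    return HeatmapMatrix(
        row_labels=[p.structure_id for p in profiles],
        column_labels=[f"{c}:{n}" for c, n in keys],
        values=np.array(rows),
        color_scheme="red_yellow_blue",
        normalization="none",
    )


def read_rmsf_csv(
    path: str | Path, structure_id: str | None = None, kind: str = "rmsf"
) -> FlexProfile:
    """Two-column (residue, value) or three-column (chain, residue, value) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] == 2:
        residues = [("A", int(r), float(v)) for r, v in df.itertuples(index=False)]
    elif df.shape[1] == 3:
        residues = [(str(c), int(r), float(v)) for c, r, v in df.itertuples(index=False)]
    else:
        raise ValueError(f"{Path(path).name}: expected 2 or 3 columns, got {df.shape[1]}")
    return FlexProfile(
        structure_id=structure_id or Path(path).stem, kind=kind, residues=residues
    )


def profile_to_csv(p: FlexProfile, path: str | Path) -> None:
    pd.DataFrame(p.residues, columns=["chain", "residue", "value"]).to_csv(path, index=False)
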