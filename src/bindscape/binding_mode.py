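"""Binding-mode fingerprints, distance metrics and heatmap matrices.

A binding mode is represented as a sparse map from interaction partner
(residue or ligand atom) to interaction strength -- energies in kcal/mol
when derived from docking tables, dimensionless counts or weights when
derived from detected contacts.  Two modes P = {p_i} and Q = {q_i} are
compared after aligning on the union of their keys (a partner absent
from one mode contributes zero strength):

* binding-mode RMSD:  sqrt( (1/n) * sum_i (p_i - q_i)^2 )
* Manhattan distance: sum_i |p_i - q_i|
* Euclidean distance: sqrt( sum_i (p_i - q_i)^2 )
* additive (signed):  sum_i (p_i - q_i) -- the balance of contributions;
  the sign reports which mode binds more strongly overall.
"""

from __future__ import annotations

import json
import math
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BindingFingerprint",
    "HeatmapMatrix",
    "EnergyRecord",
    "align_fingerprints",
    "rmsd_bm",
    "mode_distance",
    "rank_keys",
    "build_heatmap",
    "heatmap_to_csv",
    "heatmap_from_csv",
    "ingest_energy_table",
    "series_extremum",
    "records_to_frame",
]


@dataclass
class BindingFingerprint:
    """Sparse binding mode: interaction partner -> strength."""

    ligand_id: str
    entries: dict[str, float]
    source: str = "contacts"  # contacts | energy_table

    def __post_init__(self) -> None:
        for k, v in self.entries.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite strength for key {k!r}")

    def to_json(self) -> str:
        return json.dumps(
            {"ligand_id": self.ligand_id, "source": self.source, "entries": self.entries},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BindingFingerprint":
        d = json.loads(text)
        return cls(ligand_id=d["ligand_id"], entries=d["entries"], source=d["source"])


@dataclass
class HeatmapMatrix:
    """Export-ready matrix with row/column labels and colour metadata."""

    row_labels: list[str]
    column_labels: list[str]
    values: np.ndarray
    color_scheme: str = "red_yellow_green"
    normalization: str = "none"  # none | per_matrix | per_row

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.column_labels)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.column_labels)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("heatmap values must be finite")


@dataclass
class EnergyRecord:
    """One row of a docking-energy table (all energies in kcal/mol)."""

    ligand_label: str
    series: str | None
    e_protein_ligand: float
    e_total: float
    steric: float
    vdw: float
    hbond: float
    binding_affinity: float
    ligand_id: str | None = None


def align_fingerprints(
    p: BindingFingerprint, q: BindingFingerprint
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Vectors over the sorted union of keys; missing entries are 0."""
    keys = sorted(set(p.entries) | set(q.entries))
    P = np.array([p.entries.get(k, 0.0) for k in keys])
    Q = np.array([q.entries.get(k, 0.0) for k in keys])
    return P, Q, keys


def rmsd_bm(p: BindingFingerprint, q: BindingFingerprint) -> float:
    """Root-mean-square deviation between two binding modes."""
    P, Q, keys = align_fingerprints(p, q)
    if len(keys) == 0:
        raise ValueError("no interactions to compare")
    return float(np.sqrt(np.mean((P - Q) ** 2)))


def mode_distance(p: BindingFingerprint, q: BindingFingerprint, metric: str) -> float:
    """Manhattan / Euclidean / additive distance between binding modes."""
    P, Q, keys = align_fingerprints(p, q)
    if len(keys) == 0:
        raise ValueError("no interactions to compare")
    diff = P - Q
    if metric == "manhattan":
        return float(np.sum(np.abs(diff)))
    if metric == "euclidean":
        return float(np.sqrt(np.sum(diff**2)))
    if metric == "additive":
        return float(np.sum(diff))
    raise ValueError(f"unknown metric {metric!r}; expected manhattan|euclidean|additive")


def rank_keys(fingerprints: Sequence[BindingFingerprint]) -> list[str]:
    """Keys sorted by descending mean |strength| across all fingerprints.

    A partner not touched by a ligand contributes zero to its mean.
    Ties are broken lexicographically, so ranking is deterministic.
    """
    if not fingerprints:
        raise ValueError("need at least one fingerprint")
    keys = sorted({k for fp in fingerprints for k in fp.entries})
    mean_mag = {
        k: float(np.mean([abs(fp.entries.get(k, 0.0)) for fp in fingerprints])) for k in keys
    }
    return sorted(keys, key=lambda k: (-mean_mag[k], k))


def _normalize(values: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "none":
        return values
    if normalization == "per_matrix":
        m = np.max(np.abs(values))
        return values / m if m > 0 else values
    if normalization == "per_row":
        out = values.copy()
        for i in range(out.shape[0]):
            m = np.max(np.abs(out[i]))
            if m > 0:
                out[i] = out[i] / m
        return out
    raise ValueError(f"unknown normalization {normalization!r}")


def build_heatmap(
    data: Sequence[BindingFingerprint] | pd.DataFrame,
    rows: Sequence[str] | None = None,
    cols: Sequence[str] | None = None,
    normalization: str = "none",
    color_scheme: str = "red_yellow_green",
) -> HeatmapMatrix:
    """Matrix view of binding modes (rows: partners, columns: ligands).

    With a list of fingerprints, rows default to :func:`rank_keys` order
    and columns to ligand ids.  A :class:`pandas.DataFrame` (e.g. an
    energy table in wide form) is used as-is, preserving its row order.
    """
    if isinstance(data, pd.DataFrame):
        df = data
        row_labels = [str(r) for r in df.index] if rows is None else list(rows)
        col_labels = [str(c) for c in df.columns] if cols is None else list(cols)
        values = df.to_numpy(dtype=float)
    else:
        fps = list(data)
        if not fps:
            raise ValueError("no fingerprints given")
        row_labels = list(rows) if rows is not None else rank_keys(fps)
        col_labels = list(cols) if cols is not None else [fp.ligand_id for fp in fps]
        if len(col_labels) != len(fps):
            raise ValueError("cols length does not match number of fingerprints")
        values = np.array(
            [[fp.entries.get(key, 0.0) for fp in fps] for key in row_labels]
        )
    if values.shape != (len(row_labels), len(col_labels)):
        raise ValueError("ragged input: values shape does not match labels")
    return HeatmapMatrix(
        row_labels=row_labels,
        column_labels=col_labels,
        values=_normalize(values, normalization),
        color_scheme=color_scheme,
        normalization=normalization,
    )


def heatmap_to_csv(hm: HeatmapMatrix, path: str | Path) -> None:
    # repr(float) is the shortest round-tripping representation, so the
    # CSV round trip is bit-exact
    with open(path, "w") as fh:
        fh.write("," + ",".join(hm.column_labels) + "\n")
        for label, row in zip(hm.row_labels, hm.values):
            fh.write(label + "," + ",".join(repr(float(v)) for v in row) + "\n")


def heatmap_from_csv(
    path: str | Path, color_scheme: str = "red_yellow_green", normalization: str = "none"
) -> HeatmapMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return HeatmapMatrix(
        row_labels=[str(r) for r in df.index],
        column_labels=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        color_scheme=color_scheme,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# energy-table ingestion (docking output; energies in kcal/mol)

_COLUMN_ALIASES: dict[str, list[str]] = {
    "ligand": ["ligand"],
    "e_protein_ligand": ["e_protein-ligand", "e_protein_ligand", "e_proteinligand", "eproteinligand"],
    "e_total": ["e_total", "etotal"],
    "steric": ["steric"],
    "vdw": ["van der waals", "vdw", "vanderwaals"],
    "hbond": ["hydrogen bond", "hydrogen bonds", "hbond", "hbonds"],
    "binding_affinity": ["binding affinity", "bindingaffinity"],
}
_SERIES_ALIASES = ["glycone", "series"]

_GLYCONE_TO_SERIES = {
    "-": "none",
    "": "none",
    "none": "none",
    "ribose": "ribose",
    "2'-deoxyribose": "deoxyribose",
    "deoxyribose": "deoxyribose",
    "2'-deoxy-2',2'-difluoro-ribose": "difluoro",
    "difluoro": "difluoro",
}

_MINUS_CHARS = "−–—"  # unicode minus / en dash / em dash


def _ascii_minus(text: str) -> str:
    for ch in _MINUS_CHARS:
        text = text.replace(ch, "-")
    return text


def _norm_header(name: str) -> str:
    name = unicodedata.normalize("NFKC", _ascii_minus(str(name))).strip().lower()
    name = re.sub(r"[_′']", lambda m: "'" if m.group() in "′'" else "_", name)
    return name.strip("_ ")


def ingest_energy_table(path: str | Path, sep: str | None = None) -> list[EnergyRecord]:
    """Read a delimited docking-energy table into typed records.

    Expected columns (case-insensitive, unicode minus tolerated):
    ``Ligand``, ``E_protein-ligand``, ``E_total``, ``Steric``,
    ``van der Waals``, ``Hydrogen Bond(s)``, ``Binding Affinity`` and an
    optional ``Glycone``/``Series`` column from which the glycone series
    is inferred.  A missing required column or a non-numeric cell raises
    :class:`ValueError` naming the offender.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    norm_cols = {_norm_header(c): c for c in df.columns}

    resolved: dict[str, str] = {}
    for field_name, aliases in _COLUMN_ALIASES.items():
        found = next((norm_cols[a] for a in aliases if a in norm_cols), None)
        if found is None:
            raise ValueError(f"missing required column {aliases[0]!r} in {path.name}")
        resolved[field_name] = found
    series_col = next((norm_cols[a] for a in _SERIES_ALIASES if a in norm_cols), None)

    from bindscape.ligands import LABEL_TO_PATTERN, Series, ligand_id

    def parse_num(raw, row: int, col: str) -> float:
        txt = _ascii_minus(str(raw)).strip()
        try:
            return float(txt)
        except ValueError:
            raise ValueError(f"non-numeric cell at row {row}, column {col!r}: {raw!r}") from None

    records: list[EnergyRecord] = []
    current_series: str | None = None
    for i, row in df.iterrows():
        if series_col is not None:
            raw_series = row[series_col]
            if isinstance(raw_series, str) and raw_series.strip():
                key = _ascii_minus(raw_series.strip()).replace("′", "'").lower()
                current_series = _GLYCONE_TO_SERIES.get(key, raw_series.strip())
        label = _ascii_minus(str(row[resolved["ligand"]]).strip())
        pattern = LABEL_TO_PATTERN.get(label)
        lid = None
        if pattern is not None and current_series in {s.value for s in Series}:
            lid = ligand_id(pattern, current_series)
        records.append(
            EnergyRecord(
                ligand_label=label,
                series=current_series,
                e_protein_ligand=parse_num(row[resolved["e_protein_ligand"]], i, "E_protein-ligand"),
                e_total=parse_num(row[resolved["e_total"]], i, "E_total"),
                steric=parse_num(row[resolved["steric"]], i, "Steric"),
                vdw=parse_num(row[resolved["vdw"]], i, "van der Waals"),
                hbond=parse_num(row[resolved["hbond"]], i, "Hydrogen Bond"),
                binding_affinity=parse_num(row[resolved["binding_affinity"]], i, "Binding Affinity"),
                ligand_id=lid,
            )
        )
    return records


def records_to_frame(records: Sequence[EnergyRecord]) -> pd.DataFrame:
    """Wide DataFrame of the energy components (one row per ligand)."""
    return pd.DataFrame(
        {
            "ligand": [r.ligand_label for r in records],
            "series": [r.series for r in records],
            "e_protein_ligand": [r.e_protein_ligand for r in records],
            "e_total": [r.e_total for r in records],
            "steric": [r.steric for r in records],
            "vdw": [r.vdw for r in records],
            "hbond": [r.hbond for r in records],
            "binding_affinity": [r.binding_affinity for r in records],
        }
    )


def series_extremum(
    records: Sequence[EnergyRecord],
    series: str | None = None,
    field_name: str = "binding_affinity",
    mode: str = "min",
):
    """Extremal record(s) of one energy field, optionally within a series.

    Returns ``(ligand_label, value)``; with ties, the first element is
    the list of all tied labels.
    """
    if mode not in {"min", "max"}:
        raise ValueError(f"mode must be min or max, got {mode!r}")
    pool = [r for r in records if series is None or r.series == series]
    if not pool:
        raise ValueError(f"no records left after filtering series={series!r}")
    values = [getattr(r, field_name) for r in pool]
    best = min(values) if mode == "min" else max(values)
    labels = [r.ligand_label for r, v in zip(pool, values) if v == best]
    return (labels[0] if len(labels) == 1 else labels, best)
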