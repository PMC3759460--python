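"""Reading and writing Cα traces and per-decoy score tables.

All structural scores in this package operate on Cα coordinates only, so a
structure is represented as an ordered Cα trace with residue numbers.  PDB
input goes through :mod:`gemmi`; only ``ATOM`` records are considered and the
first chain of the first model is used unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "CAStructure",
    "DecoySet",
    "ScoreTable",
    "StructureError",
    "read_pdb_ca",
    "write_pdb_ca",
    "load_decoy_set",
    "read_score_table",
    "write_score_table",
]


class StructureError(ValueError):
    """Raised for malformed or unusable structural input."""


@dataclass
class CAStructure:
    """An ordered Cα trace of one protein model.

    Parameters
    ----------
    id : str
        Identifier (usually the file stem of the decoy).
    coords : (L, 3) ndarray
        Cα coordinates in Å, ordered by residue number.
    resseq : (L,) ndarray of int
        Strictly increasing residue sequence numbers (1-based PDB numbering).
    """

    id: str
    coords: np.ndarray
    resseq: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.resseq = np.asarray(self.resseq, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError(f"{self.id}: coords must be (L, 3)")
        if len(self.coords) != len(self.resseq):
            raise StructureError(f"{self.id}: coords and resseq length mismatch")
        if len(self.coords) < 4:
            raise StructureError(
                f"{self.id}: need at least 4 residues, got {len(self.coords)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"{self.id}: non-finite coordinates")
        if np.any(np.diff(self.resseq) <= 0):
            raise StructureError(f"{self.id}: residue numbers not strictly increasing")

    def __len__(self) -> int:
        return len(self.resseq)

    def restrict(self, resseq: Iterable[int]) -> "CAStructure":
        """Return a copy restricted to the given residue numbers (kept in order)."""
        keep = np.asarray(sorted(set(resseq)), dtype=int)
        mask = np.isin(self.resseq, keep)
        if mask.sum() < 4:
            raise StructureError(
                f"{self.id}: fewer than 4 residues after restriction"
            )
        return CAStructure(self.id, self.coords[mask], self.resseq[mask])


@dataclass
class DecoySet:
    """All decoys of one target, with optional native structure and true GDT."""

    target_id: str
    decoys: list[CAStructure]
    native: Optional[CAStructure] = None
    true_gdt: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if len(self.decoys) < 2:
            raise StructureError(
                f"{self.target_id}: a decoy set needs at least 2 decoys"
            )
        lengths = {len(d) for d in self.decoys}
        if len(lengths) != 1:
            raise StructureError(
                f"{self.target_id}: decoys have differing lengths {sorted(lengths)}"
            )
        if (self.native is None) != (self.true_gdt is None):
            raise StructureError(
                f"{self.target_id}: true_gdt must be present iff native is present"
            )
        if self.true_gdt is not None:
            missing = {d.id for d in self.decoys} - set(self.true_gdt)
            if missing:
                raise StructureError(
                    f"{self.target_id}: true_gdt missing decoys {sorted(missing)}"
                )

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self.decoys]

    @property
    def length(self) -> int:
        return len(self.decoys[0])


@dataclass
class ScoreTable:
    """A named per-decoy score column.

    ``orientation`` records whether larger values mean better models
    ("higher") or worse models ("lower", e.g. energies).
    """

    name: str
    values: dict[str, float]
    orientation: str = "higher"

    def __post_init__(self) -> None:
        if self.orientation not in ("higher", "lower"):
            raise ValueError(f"orientation must be 'higher' or 'lower', got {self.orientation!r}")
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"score table {self.name}: non-finite value for {k!r}")

    def oriented(self) -> "ScoreTable":
        """Return a higher-is-better copy (negates lower-is-better values)."""
        if self.orientation == "higher":
            return ScoreTable(self.name, dict(self.values), "higher")
        return ScoreTable(self.name, {k: -v for k, v in self.values.items()}, "higher")

    def as_series(self, ids: Optional[Iterable[str]] = None) -> pd.Series:
        if ids is None:
            ids = sorted(self.values)
        return pd.Series([self.values[i] for i in ids], index=list(ids), name=self.name)


def read_pdb_ca(
    path: str | Path,
    model_policy: str = "first",
    chain: Optional[str] = None,
    id: Optional[str] = None,
) -> CAStructure:
    """Read the Cα trace of one chain from a PDB file.

    Only ``ATOM`` records are used; HETATM groups are ignored.  Alternate
    locations resolve to the first listed conformer.  ``model_policy`` is
    ``"first"`` (take model 1) or ``"error"`` (reject multi-model files).
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models in file")
    if model_policy == "error" and len(st) > 1:
        raise StructureError(f"{path}: file has {len(st)} models")
    if model_policy not in ("first", "error"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    model = st[0]
    if len(model) == 0:
        raise StructureError(f"{path}: no chains")
    if chain is None:
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise StructureError(f"{path}: chain {chain!r} not found")

    seen: dict[int, np.ndarray] = {}
    order: list[int] = []
    for res in ch:
        if res.het_flag == "H":
            continue
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            continue
        num = res.seqid.num
        first = np.array([cas[0].pos.x, cas[0].pos.y, cas[0].pos.z])
        for other in cas[1:]:
            # altloc conformers resolve to the first listed; a repeated plain
            # ATOM record with different coordinates is ambiguous
            oxyz = np.array([other.pos.x, other.pos.y, other.pos.z])
            if other.altloc == "\0" and cas[0].altloc == "\0" and not np.allclose(first, oxyz, atol=1e-6):
                raise StructureError(
                    f"{path}: duplicate residue {num} with differing CA coordinates"
                )
        xyz = first
        if num in seen:
            if not np.allclose(seen[num], xyz, atol=1e-6):
                raise StructureError(
                    f"{path}: duplicate residue {num} with differing CA coordinates"
                )
            continue
        seen[num] = xyz
        order.append(num)
    if not seen:
        raise StructureError(f"{path}: no CA atoms found")
    if len(seen) < 4:
        raise StructureError(f"{path}: fewer than 4 CA residues")
    nums = sorted(order)
    coords = np.array([seen[n] for n in nums])
    return CAStructure(id or path.stem, coords, np.array(nums))


def write_pdb_ca(s: CAStructure, path: str | Path) -> None:
    """Write a Cα trace as a minimal single-chain PDB file (poly-ALA)."""
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model(1)
    ch = gemmi.Chain("A")
    for num, xyz in zip(s.resseq, s.coords):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(num), " ")
        res.het_flag = "A"
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, xyz))
        res.add_atom(atom)
        ch.add_residue(res)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def load_decoy_set(
    directory: str | Path,
    native: Optional[str | Path] = None,
    target_id: Optional[str] = None,
) -> DecoySet:
    """Load all ``*.pdb`` files of a directory as one decoy set.

    Decoy ids are file stems, ordered lexicographically.  Structures whose
    residue numbering differs are restricted to the common residue-number
    intersection; an intersection below 4 residues is an error.  When a
    native file is given, true GDT-TS of every decoy against it is computed.
    """
    from .gdt import gdt_ts  # local import: gdt depends on these types

    directory = Path(directory)
    files = sorted(directory.glob("*.pdb"))
    if native is not None:
        native = Path(native)
        files = [f for f in files if f.resolve() != native.resolve()]
    if len(files) < 2:
        raise StructureError(f"{directory}: need at least 2 decoy PDB files, found {len(files)}")
    decoys = [read_pdb_ca(f) for f in files]
    native_s = read_pdb_ca(native, id="native") if native is not None else None

    common = set(decoys[0].resseq.tolist())
    for d in decoys[1:]:
        common &= set(d.resseq.tolist())
    if native_s is not None:
        common &= set(native_s.resseq.tolist())
    if len(common) < 4:
        raise StructureError(f"{directory}: common residue intersection below 4 residues")
    if any(len(d) != len(common) for d in decoys) or (
        native_s is not None and len(native_s) != len(common)
    ):
        decoys = [d.restrict(common) for d in decoys]
        if native_s is not None:
            native_s = native_s.restrict(common)

    true_gdt = None
    if native_s is not None:
        true_gdt = {d.id: gdt_ts(d, native_s) for d in decoys}
    return DecoySet(target_id or directory.name, decoys, native_s, true_gdt)


def read_score_table(path: str | Path, name: str, orientation: str = "higher") -> ScoreTable:
    """Read a two-column ``decoy_id<TAB>score`` TSV (header optional)."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][0] in ("decoy_id", "id") :
        rows = rows[1:]
    values: dict[str, float] = {}
    for decoy_id, raw in rows:
        try:
            v = float(raw)
        except ValueError:
            raise ValueError(f"{path}: non-numeric score {raw!r} for row {decoy_id!r}") from None
        if not math.isfinite(v):
            raise ValueError(f"{path}: non-finite score for row {decoy_id!r}")
        if decoy_id in values:
            raise ValueError(f"{path}: duplicate decoy id {decoy_id!r}")
        values[decoy_id] = v
    if not values:
        raise ValueError(f"{path}: empty score table")
    return ScoreTable(name, values, orientation)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table as TSV, ids sorted, full float precision."""
    with open(path, "w") as fh:
        fh.write("decoy_id\tscore\n")
        for decoy_id in sorted(table.values):
            fh.write(f"{decoy_id}\t{table.values[decoy_id]!r}\n")
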