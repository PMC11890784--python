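"""Structure and ensemble I/O.

Reads and writes fixed-column PDB files, including multi-model (MODEL/ENDMDL)
conformer ensembles, selects network nodes (Cα for amino-acid residues, P for
nucleotides), and maps per-residue scalar fields back into the B-factor column.

Residue identity is the triple ``(chain, resseq, icode)`` and is preserved
verbatim — residues are never renumbered. Alternate locations are resolved at
parse time by keeping the highest-occupancy conformer (ties prefer altloc
``'A'``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "StructureModel",
    "TrajectoryEnsemble",
    "Node",
    "NodeSet",
    "PDBFormatError",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "select_nodes",
    "write_bfactors",
    "AMINO_ACIDS",
    "NUCLEOTIDES",
]

#: Standard amino acids plus common variants (selenomethionine, protonation
#: states used by MD force fields, capped cysteines).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
    "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX", "CYM", "ASH", "GLH", "LYN",
}

#: DNA/RNA residue names (one- and two-letter conventions).
NUCLEOTIDES = {
    "DA", "DT", "DG", "DC", "DU", "DI",
    "A", "T", "G", "C", "U", "I",
    "RA", "RU", "RG", "RC",
}

_WATER = {"HOH", "WAT", "TIP", "TIP3", "SPC"}


class PDBFormatError(ValueError):
    """Raised for malformed PDB input."""


@dataclass(frozen=True)
class Atom:
    """One atom record. Coordinates live in the parent model's array."""

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    occupancy: float
    bfactor: float
    element: str
    het: bool = False

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)


@dataclass
class StructureModel:
    """Ordered atoms plus an (A, 3) coordinate array in Å."""

    atoms: list[Atom]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Residues in file order as ``(residue_id, atom_indices)``."""
        out: list[tuple[tuple[str, int, str], list[int]]] = []
        index: dict[tuple[str, int, str], list[int]] = {}
        for i, atom in enumerate(self.atoms):
            rid = atom.residue_id
            if rid not in index:
                index[rid] = []
                out.append((rid, index[rid]))
            index[rid].append(i)
        return out

    def atom_identity(self) -> list[tuple[str, int, str, str]]:
        return [(a.chain, a.resseq, a.icode, a.name) for a in self.atoms]


@dataclass
class TrajectoryEnsemble:
    """Conformer ensemble: fixed topology + (F, A, 3) coordinate frames."""

    topology: StructureModel
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (
            self.topology.n_atoms,
            3,
        ):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms} topology atoms"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def subset_frames(self, sl: slice) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(self.topology, self.frames[sl].copy())


@dataclass(frozen=True)
class Node:
    """A network node: one polymer residue with its representative atom."""

    chain: str
    resseq: int
    icode: str
    kind: str  # "protein" | "nucleic"
    atom_index: int

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain}:{self.resseq}{self.icode.strip()}"


@dataclass
class NodeSet:
    """Ordered network nodes (chain order, then residue order)."""

    nodes: list[Node]

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def __getitem__(self, i: int) -> Node:
        return self.nodes[i]

    @property
    def atom_indices(self) -> np.ndarray:
        return np.array([n.atom_index for n in self.nodes], dtype=int)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]


# ---------------------------------------------------------------------------
# parsing

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, tuple[float, float, float]]:
    het = line.startswith("HETATM")
    line = line.rstrip("\n")
    if len(line) < 54:
        raise PDBFormatError(
            f"line {lineno}: ATOM/HETATM record too short ({len(line)} columns)"
        )

    def _float(cols: slice, what: str, default: float | None = None) -> float:
        text = line[cols].strip()
        if not text and default is not None:
            return default
        try:
            return float(text)
        except ValueError:
            raise PDBFormatError(
                f"line {lineno}: non-numeric {what} field {text!r}"
            ) from None

    try:
        serial = int(line[6:11].strip() or 0)
    except ValueError:
        raise PDBFormatError(
            f"line {lineno}: non-numeric serial {line[6:11].strip()!r}"
        ) from None
    name = line[12:16].strip()
    altloc = line[16]
    resname = line[17:20].strip()
    chain = line[21]
    try:
        resseq = int(line[22:26].strip())
    except ValueError:
        raise PDBFormatError(
            f"line {lineno}: non-numeric residue number {line[22:26].strip()!r}"
        ) from None
    icode = line[26] if len(line) > 26 else " "
    x = _float(slice(30, 38), "x")
    y = _float(slice(38, 46), "y")
    z = _float(slice(46, 54), "z")
    occ = _float(slice(54, 60), "occupancy", default=1.0) if len(line) > 54 else 1.0
    bf = _float(slice(60, 66), "b-factor", default=0.0) if len(line) > 60 else 0.0
    element = line[76:78].strip() if len(line) > 76 else ""
    if not element:
        element = _guess_element(name, resname)
    atom = Atom(serial, name, altloc, resname, chain, resseq, icode, occ, bf,
                element, het)
    return atom, (x, y, z)


def _guess_element(name: str, resname: str) -> str:
    """Infer the element from the atom name (standard PDB conventions)."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        return ""
    two = stripped[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "CL", "BR", "NA", "CA"} and len(name) >= 2:
        # "CA" is calcium only for the CA ion residue; in polymers it is Cα.
        if two == "CA" and resname not in {"CA"}:
            return "C"
        return two.capitalize()
    return stripped[0].upper()


def _resolve_altlocs(atoms: list[Atom], coords: list[tuple[float, float, float]]
                     ) -> tuple[list[Atom], list[tuple[float, float, float]]]:
    """Keep one altloc per (residue, atom name): highest occupancy, tie → 'A'."""
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    for i, a in enumerate(atoms):
        key = (a.chain, a.resseq, a.icode, a.name)
        if key not in best:
            best[key] = i
            order.append(key)
        else:
            j = best[key]
            b = atoms[j]
            if (a.occupancy, _altloc_rank(a.altloc)) > (
                b.occupancy, _altloc_rank(b.altloc)
            ):
                best[key] = i
    kept = sorted(best.values())
    return [atoms[i] for i in kept], [coords[i] for i in kept]


def _altloc_rank(altloc: str) -> int:
    # Higher is preferred at equal occupancy: blank beats 'A' beats 'B'...
    if altloc == " " or altloc == "":
        return 1000
    return 999 - (ord(altloc) - ord("A"))


def _read_models(path: str | Path) -> list[StructureModel]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    models: list[StructureModel] = []
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    saw_model_record = False
    in_model = False

    def _flush() -> None:
        nonlocal atoms, coords
        if atoms:
            a, c = _resolve_altlocs(atoms, coords)
            models.append(StructureModel(a, np.array(c, dtype=float)))
        atoms, coords = [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model_record = True
                _flush()
                in_model = True
            elif rec.startswith("ENDMDL"):
                _flush()
                in_model = False
            elif rec.startswith(("ATOM  ", "HETATM")):
                atom, xyz = _parse_atom_line(line, lineno)
                atoms.append(atom)
                coords.append(xyz)
            # TER / REMARK / everything else: ignored
    _flush()
    if not models:
        raise PDBFormatError(f"{path}: no atoms found (empty or non-PDB file)")
    if saw_model_record and in_model:
        logger.warning("%s: final MODEL block not closed by ENDMDL", path)
    return models


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB file; multi-model files yield the first model (warned)."""
    models = _read_models(path)
    if len(models) > 1:
        logger.warning(
            "%s: %d models present; returning the first", path, len(models)
        )
    return models[0]


def read_ensemble(path: str | Path) -> TrajectoryEnsemble:
    """Parse a multi-model PDB into a TrajectoryEnsemble.

    The topology is taken from the first model; every subsequent model must
    list the same atoms in the same order.
    """
    models = _read_models(path)
    top = models[0]
    ident = top.atom_identity()
    frames = np.empty((len(models), top.n_atoms, 3), dtype=float)
    for m, model in enumerate(models):
        if model.n_atoms != top.n_atoms:
            raise PDBFormatError(
                f"model {m + 1}: {model.n_atoms} atoms, expected {top.n_atoms}"
            )
        if model.atom_identity() != ident:
            raise PDBFormatError(
                f"model {m + 1}: atom order differs from model 1"
            )
        frames[m] = model.coords
    return TrajectoryEnsemble(top, frames)


# ---------------------------------------------------------------------------
# writing

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    # One-letter elements start in column 14 by convention.
    if len(element) == 1 or (element == "" and len(name) <= 3):
        return f" {name:<3s}"
    return f"{name:<4s}"


def _atom_line(atom: Atom, xyz: np.ndarray, serial: int,
               bfactor: float | None = None) -> str:
    rec = "HETATM" if atom.het else "ATOM  "
    b = atom.bfactor if bfactor is None else bfactor
    return (
        f"{rec}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
        f"{atom.altloc if atom.altloc.strip() else ' '}"
        f"{atom.resname:>3s} {atom.chain}{atom.resseq:4d}{atom.icode}"
        f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{atom.occupancy:6.2f}{b:6.2f}          {atom.element:>2s}\n"
    )


def write_structure(model: StructureModel, path: str | Path,
                    bfactors: np.ndarray | None = None) -> Path:
    """Write a single-model PDB; optional per-atom B-factor override."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, atom in enumerate(model.atoms):
            b = None if bfactors is None else float(bfactors[i])
            fh.write(_atom_line(atom, model.coords[i], (i % 99999) + 1, b))
        fh.write("END\n")
    return path


def write_ensemble(ensemble: TrajectoryEnsemble, path: str | Path) -> Path:
    """Write a multi-model PDB, one MODEL/ENDMDL block per frame."""
    path = Path(path)
    top = ensemble.topology
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL {f + 1:8d}\n")
            frame = ensemble.frames[f]
            for i, atom in enumerate(top.atoms):
                fh.write(_atom_line(atom, frame[i], (i % 99999) + 1))
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


# ---------------------------------------------------------------------------
# node selection

def select_nodes(model: StructureModel) -> NodeSet:
    """One node per polymer residue: Cα for amino acids, P for nucleotides.

    Residues lacking their representative atom (e.g. 5′-terminal nucleotides,
    which carry no phosphate) are skipped with a warning. HETATM-only
    residues, waters and ligands contribute no nodes.
    """
    nodes: list[Node] = []
    for rid, atom_idx in model.residues():
        first = model.atoms[atom_idx[0]]
        resname = first.resname
        if resname in _WATER:
            continue
        if resname in AMINO_ACIDS:
            kind, rep = "protein", "CA"
        elif resname in NUCLEOTIDES:
            kind, rep = "nucleic", "P"
        else:
            continue
        if all(model.atoms[i].het for i in atom_idx):
            continue
        rep_idx = next(
            (i for i in atom_idx if model.atoms[i].name == rep), None
        )
        if rep_idx is None:
            logger.warning(
                "residue %s:%s%s (%s) lacks representative atom %s; skipped",
                rid[0], rid[1], rid[2].strip(), resname, rep,
            )
            continue
        nodes.append(Node(rid[0], rid[1], rid[2], kind, rep_idx))
    if not nodes:
        logger.warning("node selection produced an empty NodeSet")
    return NodeSet(nodes)


# ---------------------------------------------------------------------------
# B-factor mapping

def write_bfactors(
    model: StructureModel,
    values: Mapping[tuple, float],
    path: str | Path,
) -> Path:
    """Write the model with per-residue scalars in the B-factor column.

    ``values`` is keyed by ``(chain, resseq)`` or ``(chain, resseq, icode)``;
    every atom of a keyed residue carries that value (%6.2f, clamped to
    [0, 999.99] with a warning); atoms of unkeyed residues get 0.00.
    """
    normalized: dict[tuple[str, int, str], float] = {}
    for key, v in values.items():
        if len(key) == 2:
            key = (key[0], key[1], " ")
        v = float(v)
        if math.isnan(v):
            raise ValueError(f"NaN B-factor value for residue {key}")
        clamped = min(max(v, 0.0), 999.99)
        if clamped != v:
            logger.warning(
                "B-factor %.3f for residue %s clamped to %.2f", v, key, clamped
            )
        normalized[(key[0], int(key[1]), key[2])] = clamped
    per_atom = np.zeros(model.n_atoms)
    for i, atom in enumerate(model.atoms):
        per_atom[i] = normalized.get(atom.residue_id, 0.0)
    return write_structure(model, path, bfactors=per_atom)
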