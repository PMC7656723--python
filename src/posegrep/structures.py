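"""Receptor and docked-pose file I/O.

Reads the three docked-pose formats produced by common docking pipelines
(PDBQT from AutoDock Vina, plain PDB, and MDL SDF/V2000) plus PDB/PDBQT
receptor structures, and exposes them as typed atom collections.  Multi-pose
PDB/PDBQT files are split on MODEL/ENDMDL records; SDF files are split on
``$$$$`` delimiters and keep their bond blocks.

No coordinate transformation is ever applied: receptor and poses are assumed
to share the docking run's frame of reference.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("posegrep")

# Single / double / triple / aromatic bond orders as stored on pose graphs.
BOND_SINGLE = 1
BOND_DOUBLE = 2
BOND_TRIPLE = 3
BOND_AROMATIC = 4

_VALID_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu",
    "Zn", "As", "Se", "Br", "Kr", "Mo", "Ru", "Rh", "Pd", "Ag", "Cd", "Sn",
    "Sb", "Te", "I", "Xe", "Pt", "Au", "Hg", "Pb", "Bi",
}

# AutoDock atom types that are not plain element symbols.
_AUTODOCK_TYPE_TO_ELEMENT = {
    "A": "C",    # aromatic carbon
    "OA": "O", "OS": "O",
    "NA": "N", "NS": "N",
    "SA": "S",
    "HD": "H", "HS": "H",
}


class StructureError(Exception):
    """Fatal problem with a receptor or configuration input."""


@dataclass(frozen=True)
class Atom:
    """One named point particle with PDB-style identity."""

    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    chain: str = ""
    resid: int = 0
    resname: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def __post_init__(self) -> None:
        if len(self.coords) != 3 or not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"atom {self.serial}: coords must be 3 finite numbers")

    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class Receptor:
    """The target structure, addressable by (chain, resid, atom name)."""

    atoms: list[Atom]
    source_path: str = ""
    format: str = "PDB"
    _index: dict[tuple[str, int, str], Atom] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        index: dict[tuple[str, int, str], Atom] = {}
        for atom in self.atoms:
            key = (atom.chain, atom.resid, atom.name)
            if key in index:
                raise StructureError(
                    f"{self.source_path or 'receptor'}: duplicate atom selector "
                    f"(chain={key[0]!r}, resid={key[1]}, atomname={key[2]!r})"
                )
            index[key] = atom
        self._index = index

    def select_atom(self, chain: str, resid: int, atomname: str) -> Atom:
        """Resolve a (chain, resid, atomname) triple to the unique matching atom.

        A selector that cannot be anchored is a fatal configuration error:
        a filter anchored to a missing atom must abort the run rather than
        silently pass everything.
        """
        key = (chain, int(resid), atomname)
        try:
            return self._index[key]
        except KeyError:
            raise StructureError(
                f"receptorAtom selector not found in {self.source_path or 'receptor'}: "
                f"chain={chain!r}, resid={resid}, atomname={atomname!r}"
            ) from None


@dataclass
class PoseRecord:
    """One docked pose: atoms, optional bonds, and file provenance.

    ``bonds`` holds (i, j, order) triples with 0-based atom indices.  It is
    populated directly for SDF input (the format carries a bond block) and
    left ``None`` for PDB/PDBQT until a bond-perception step runs.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] | None
    pose_index: int
    source_path: str = ""
    format: str = "PDBQT"
    title: str = ""

    def __post_init__(self) -> None:
        if self.pose_index < 1:
            raise ValueError("pose_index is 1-based")
        if self.bonds is not None:
            n = len(self.atoms)
            for i, j, _order in self.bonds:
                if not (0 <= i < n and 0 <= j < n) or i == j:
                    raise ValueError(
                        f"{self.source_path}: bond ({i},{j}) refers outside pose"
                    )

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


def _infer_element_from_name(name: str) -> str:
    """Derive the element from the PDB atom-name field.

    PDB convention left-justifies two-letter elements within columns 13-16;
    docking outputs frequently omit the element columns 77-78 so this path
    is exercised routinely.
    """
    stripped = name.strip()
    letters = "".join(c for c in stripped if c.isalpha())
    if not letters:
        return ""
    two = letters[:2].capitalize()
    if len(letters) >= 2 and two in _VALID_ELEMENTS and two not in ("Ca", "Cd", "Co", "Cu", "Ni", "Nd", "Np", "Ho", "Os"):
        # Halogens and similar genuinely two-letter organics; metal symbols
        # colliding with C/N/H/O prefixes are resolved in favour of the
        # organic single-letter reading, which is right for ligand atoms.
        if two in ("Cl", "Br", "Se", "Si", "Mg", "Zn", "Fe", "Mn"):
            return two
    one = letters[0].upper()
    return one if one in _VALID_ELEMENTS else ""


def _element_from_pdbqt_type(ad_type: str) -> str:
    t = ad_type.strip()
    if t in _AUTODOCK_TYPE_TO_ELEMENT:
        return _AUTODOCK_TYPE_TO_ELEMENT[t]
    cap = t.capitalize()
    return cap if cap in _VALID_ELEMENTS else ""


def _parse_pdb_atom_line(line: str, serial_fallback: int, fmt: str) -> Atom | None:
    """Parse one ATOM/HETATM line; returns None (with a logged warning) on a
    malformed coordinate field."""
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        logger.warning("skipping malformed coordinate line: %r", line.rstrip())
        return None
    try:
        serial = int(line[6:11])
    except (ValueError, IndexError):
        serial = serial_fallback
    name = line[12:16].strip()
    resname = line[17:20].strip()
    chain = line[21:22].strip()
    try:
        resid = int(line[22:26])
    except (ValueError, IndexError):
        resid = 0

    element = ""
    if fmt == "PDBQT":
        # PDBQT appends partial charge (cols 71-76) and AutoDock type (77-79).
        element = _element_from_pdbqt_type(line[77:80] if len(line) > 77 else "")
    if not element and len(line) >= 78:
        cand = line[76:78].strip().capitalize()
        if cand in _VALID_ELEMENTS:
            element = cand
    if not element:
        element = _infer_element_from_name(name)
    if not element:
        logger.warning("skipping line with unrecognizable element: %r", line.rstrip())
        return None
    return Atom(serial=serial, name=name, element=element, coords=(x, y, z),
                chain=chain, resid=resid, resname=resname)


def _format_of_path(path: str | Path) -> str:
    ext = Path(path).suffix.lower()
    return {".pdb": "PDB", ".pdbqt": "PDBQT", ".sdf": "SDF"}.get(ext, "")


def read_receptor(path: str | Path) -> Receptor:
    """Load a PDB or PDBQT receptor.

    All ATOM/HETATM records are kept (co-crystallized cofactors included, so
    HETATM atoms are valid receptorAtom anchors).  Malformed coordinate lines
    are skipped with a warning; a file yielding zero atoms is fatal.
    """
    path = Path(path)
    fmt = _format_of_path(path) or "PDB"
    if fmt == "SDF":
        raise StructureError(f"receptor must be PDB or PDBQT, got SDF: {path}")
    try:
        text = path.read_text()
    except OSError as exc:
        raise StructureError(f"cannot read receptor file {path}: {exc}") from exc

    atoms: list[Atom] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith(("ATOM", "HETATM")):
            atom = _parse_pdb_atom_line(line, lineno, fmt)
            if atom is not None:
                atoms.append(atom)
    if not atoms:
        raise StructureError(f"no atoms found in receptor file {path}")
    return Receptor(atoms=atoms, source_path=str(path), format=fmt)


def select_atom(receptor: Receptor, chain: str, resid: int, atomname: str) -> Atom:
    return receptor.select_atom(chain, resid, atomname)


def _read_pdb_like_poses(text: str, path: str, fmt: str) -> list[PoseRecord]:
    # MODEL/ENDMDL blocks -> one pose each; a file without MODEL records is a
    # single pose.  ROOT/BRANCH/TORSDOF PDBQT records carry no geometry and
    # are ignored.
    blocks: list[list[Atom]] = []
    current: list[Atom] = []
    saw_model = False
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith("MODEL"):
            saw_model = True
            current = []
        elif line.startswith("ENDMDL"):
            blocks.append(current)
            current = []
        elif line.startswith(("ATOM", "HETATM")):
            atom = _parse_pdb_atom_line(line, lineno, fmt)
            if atom is not None:
                current.append(atom)
    if not saw_model:
        blocks = [current]
    elif current:
        # MODEL without closing ENDMDL: keep the trailing block.
        blocks.append(current)
    blocks = [b for b in blocks if b]
    return [
        PoseRecord(atoms=b, bonds=None, pose_index=i, source_path=path, format=fmt)
        for i, b in enumerate(blocks, 1)
    ]


def _read_sdf_poses(text: str, path: str) -> list[PoseRecord]:
    """Parse MDL V2000 entries; bond block is transcribed verbatim.

    Order 4 in a V2000 bond block means aromatic.
    """
    poses: list[PoseRecord] = []
    entries = text.split("$$$$")
    idx = 0
    for entry in entries:
        lines = entry.splitlines()
        # strip leading blank lines between records
        while lines and not lines[0].strip():
            lines.pop(0)
        if len(lines) < 4:
            continue
        title = lines[0].strip()
        counts = lines[3]
        try:
            n_atoms = int(counts[0:3])
            n_bonds = int(counts[3:6])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: bad V2000 counts line {counts!r}") from exc
        atom_lines = lines[4:4 + n_atoms]
        bond_lines = lines[4 + n_atoms:4 + n_atoms + n_bonds]
        if len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
            raise ValueError(f"{path}: truncated V2000 block")
        atoms: list[Atom] = []
        for i, al in enumerate(atom_lines, 1):
            x = float(al[0:10])
            y = float(al[10:20])
            z = float(al[20:30])
            element = al[31:34].strip().capitalize()
            if element not in _VALID_ELEMENTS:
                raise ValueError(f"{path}: unknown element {element!r} in atom block")
            atoms.append(Atom(serial=i, name=f"{element}{i}", element=element,
                              coords=(x, y, z), resname="LIG", resid=1))
        bonds: list[tuple[int, int, int]] = []
        for bl in bond_lines:
            a = int(bl[0:3]) - 1
            b = int(bl[3:6]) - 1
            order = int(bl[6:9])
            bonds.append((a, b, order))
        idx += 1
        poses.append(PoseRecord(atoms=atoms, bonds=bonds, pose_index=idx,
                                source_path=path, format="SDF", title=title))
    return poses


def read_poses(path: str | Path) -> list[PoseRecord]:
    """Read all poses from one docked-compound file.

    Raises ``ValueError``/``OSError`` on unparseable input; the screening
    engine converts those into per-file skip records (warn-and-continue), so
    one corrupt file never aborts a run.  An empty file yields an empty list.
    """
    path = Path(path)
    fmt = _format_of_path(path)
    if not fmt:
        raise ValueError(f"unsupported pose file extension: {path}")
    text = path.read_text()
    if fmt == "SDF":
        return _read_sdf_poses(text, str(path))
    return _read_pdb_like_poses(text, str(path), fmt)


# ---------------------------------------------------------------------------
# Writers (used by the fixture generator and for round-trip checks)

def _pdb_atom_line(atom: Atom, record: str = "ATOM", fmt: str = "PDB",
                   charge: float = 0.0) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    line = (
        f"{record:<6s}{atom.serial:>5d} {name:<4s} "
        f"{atom.resname:>3s} {atom.chain or 'A':1s}{atom.resid:>4d}    "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}"
    )
    if fmt == "PDBQT":
        ad_type = {"C": "C", "N": "NA", "O": "OA", "H": "HD", "S": "SA"}.get(
            atom.element, atom.element)
        line += f"    {charge:6.3f} {ad_type:<2s}"
    else:
        line += f"          {atom.element:>2s}"
    return line


def write_receptor(receptor_atoms: Sequence[Atom], path: str | Path,
                   fmt: str = "PDB") -> None:
    lines = [_pdb_atom_line(a, fmt=fmt) for a in receptor_atoms]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_poses(poses: Iterable[PoseRecord], path: str | Path, fmt: str) -> None:
    """Write poses in PDB, PDBQT (MODEL/ENDMDL blocks) or SDF (V2000)."""
    path = Path(path)
    poses = list(poses)
    if fmt in ("PDB", "PDBQT"):
        out: list[str] = []
        multi = len(poses) > 1
        for pose in poses:
            if multi:
                out.append(f"MODEL {pose.pose_index:>8d}")
            out.extend(_pdb_atom_line(a, record="HETATM", fmt=fmt) for a in pose.atoms)
            out.append("ENDMDL" if multi else "END")
        path.write_text("\n".join(out) + "\n")
    elif fmt == "SDF":
        out = []
        for pose in poses:
            bonds = pose.bonds or []
            out.append(pose.title or path.stem)
            out.append("  posegrep")
            out.append("")
            out.append(f"{len(pose.atoms):>3d}{len(bonds):>3d}  0  0  0  0  0  0  0  0999 V2000")
            for a in pose.atoms:
                out.append(f"{a.coords[0]:>10.4f}{a.coords[1]:>10.4f}{a.coords[2]:>10.4f} "
                           f"{a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
            for i, j, order in bonds:
                out.append(f"{i + 1:>3d}{j + 1:>3d}{order:>3d}  0")
            out.append("M  END")
            out.append("$$$$")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown pose format {fmt!r}")


def discover_compound_files(directory: str | Path) -> list[Path]:
    """List docked-compound files by extension, case-insensitive and sorted.

    ``.smi`` companions are never treated as poses; mixed-format directories
    are permitted.
    """
    directory = Path(directory)
    out = [
        p for p in sorted(directory.iterdir(), key=lambda p: p.name)
        if p.is_file() and p.suffix.lower() in (".pdb", ".pdbqt", ".sdf")
    ]
    return out


def smiles_companion(path: str | Path) -> Path | None:
    """Locate the ``.smi`` companion of a docked-compound file.

    The convention is the pose file name plus ``.smi`` (``lig.pdbqt.smi``);
    the stem variant (``lig.smi``) is accepted as a fallback.
    """
    path = Path(path)
    for cand in (path.with_name(path.name + ".smi"), path.with_suffix(".smi")):
        if cand.exists():
            return cand
    return None
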