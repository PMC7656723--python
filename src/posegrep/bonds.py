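"""Bond assignment for docked poses.

PDB/PDBQT docked poses carry no bond information, so before a substructure
pattern can be matched a molecular graph has to be built.  Three strategies
are supported, selected by the run mode:

* ``NONE`` — geometric inference: every pair of atoms closer than the sum of
  their single-bond covalent radii (plus a tolerance) is connected by a
  single bond, and all atoms are treated as sp3.  SDF poses bypass this and
  use their own bond block.
* ``SMILES`` — the connectivity and bond orders of a user-supplied SMILES
  template are mapped onto the pose atoms by an element-labelled graph
  isomorphism against the geometric connectivity.
* ``OPENBABEL`` — an external PDB→SDF converter (Open Babel) assigns
  hybridization and bond orders; run as a subprocess, never linked in.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from rdkit import Chem
from scipy.spatial.distance import pdist, squareform

from .structures import (
    BOND_AROMATIC, BOND_SINGLE, Atom, PoseRecord, _read_sdf_poses,
)

logger = logging.getLogger("posegrep")

# Single-bond covalent radii (Å), Cordero et al. values for common elements.
DEFAULT_COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
    "Se": 1.20, "As": 1.19,
}

# Additive slack on top of r_i + r_j, sized to tolerate distorted docked
# geometries without fusing nonbonded contacts.
DEFAULT_TOLERANCE = 0.45
# Atoms closer than this are coincident-atom artifacts, never bonds.
MIN_BOND_DISTANCE = 0.4


@dataclass
class CovalentRadiusTable:
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COVALENT_RADII))
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("covalent radii must be positive")


@dataclass
class MolecularGraph:
    """Atoms plus bonds with orders; the unit SMARTS matching acts on.

    ``provenance`` records how the bonds were obtained: ``geometric`` (all
    single by construction), ``sdf_block``, ``smiles_template`` or
    ``external_tool``.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]]
    provenance: str

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError("self-bond")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index out of range: ({i},{j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond ({i},{j})")
            seen.add(key)
            if self.provenance == "geometric" and order != BOND_SINGLE:
                raise ValueError("geometric graphs carry only single bonds")

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def to_rdkit(self) -> Chem.Mol:
        """Build an RDKit molecule for substructure matching.

        Full sanitization (valence checks, kekulization) is deliberately
        skipped: docked PDBQT poses lack nonpolar hydrogens and geometric
        graphs are not valence-consistent molecules.  Aromatic flags are set
        from the bond orders so aromatic SMARTS primitives behave.
        """
        mol = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetNoImplicit(True)
            mol.AddAtom(a)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE, 4: Chem.BondType.AROMATIC}
        for i, j, order in self.bonds:
            mol.AddBond(i, j, order_map.get(order, Chem.BondType.SINGLE))
            if order == BOND_AROMATIC:
                mol.GetAtomWithIdx(i).SetIsAromatic(True)
                mol.GetAtomWithIdx(j).SetIsAromatic(True)
                mol.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
        m = mol.GetMol()
        m.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(m)
        return m


class BondPerceptionError(Exception):
    """Non-fatal: the affected compound file is skipped with a warning."""


def infer_bonds_geometric(pose: PoseRecord,
                          radii: CovalentRadiusTable | None = None) -> MolecularGraph:
    """Connect appropriately juxtaposed atoms with single bonds.

    Atoms i, j are bonded iff
    ``MIN_BOND_DISTANCE <= d(i, j) <= r_i + r_j + tolerance``.
    Atoms of unknown element get a warning and participate in no bonds.
    """
    if not pose.atoms:
        raise ValueError("pose has no atoms")
    table = radii or CovalentRadiusTable()
    n = len(pose.atoms)
    r = np.empty(n)
    known = np.ones(n, dtype=bool)
    for idx, atom in enumerate(pose.atoms):
        try:
            r[idx] = table.radii[atom.element]
        except KeyError:
            logger.warning("%s: no covalent radius for element %r; atom %d left unbonded",
                           pose.source_path, atom.element, atom.serial)
            r[idx] = 0.0
            known[idx] = False
    bonds: list[tuple[int, int, int]] = []
    if n > 1:
        dist = squareform(pdist(pose.coords_array()))
        cut = r[:, None] + r[None, :] + table.tolerance
        ok = (dist <= cut) & (dist >= MIN_BOND_DISTANCE) & known[:, None] & known[None, :]
        ii, jj = np.nonzero(np.triu(ok, k=1))
        bonds = [(int(i), int(j), BOND_SINGLE) for i, j in zip(ii, jj)]
    return MolecularGraph(atoms=list(pose.atoms), bonds=bonds, provenance="geometric")


def graph_from_sdf_pose(pose: PoseRecord) -> MolecularGraph:
    """SDF poses never pass through geometric inference: their bond block is
    authoritative."""
    if pose.bonds is None:
        raise ValueError("SDF pose without bond block")
    return MolecularGraph(atoms=list(pose.atoms), bonds=list(pose.bonds),
                          provenance="sdf_block")


def _template_graph(smiles: str) -> tuple[nx.Graph, Chem.Mol]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise BondPerceptionError(f"SMILES parse failure: {smiles!r}")
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetSymbol())
    for bond in mol.GetBonds():
        order = {Chem.BondType.SINGLE: 1, Chem.BondType.DOUBLE: 2,
                 Chem.BondType.TRIPLE: 3, Chem.BondType.AROMATIC: 4}.get(
                     bond.GetBondType(), 1)
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=order)
    return g, mol


def bonds_from_smiles_template(pose: PoseRecord, smiles: str,
                               radii: CovalentRadiusTable | None = None) -> MolecularGraph:
    """Copy a SMILES template's bond orders onto the pose atoms.

    The mapping is an element-labelled graph isomorphism between the
    template's heavy atoms and the heavy-atom subgraph of the geometric
    connectivity.  Hydrogens missing from the pose (PDBQT strips nonpolar H)
    are tolerated; hydrogens present in the pose keep their geometric single
    bonds.  Stereochemistry and formal charge are ignored — only element
    identity and connectivity constrain the match.  Any mapping is as good
    as any other: bond orders are identical across automorphic mappings.

    Raises :class:`BondPerceptionError` when the template cannot be mapped;
    the caller falls back to NONE-mode bonds with a warning.
    """
    template, _mol = _template_graph(smiles)
    geo = infer_bonds_geometric(pose, radii)

    heavy = [i for i, a in enumerate(pose.atoms) if not a.is_hydrogen]
    pose_elems = Counter(pose.atoms[i].element for i in heavy)
    tmpl_elems = Counter(d["element"] for _n, d in template.nodes(data=True))
    if pose_elems != tmpl_elems:
        raise BondPerceptionError(
            f"{pose.source_path}: heavy-atom element multiset mismatch between "
            f"pose {dict(pose_elems)} and SMILES {dict(tmpl_elems)}"
        )

    pose_graph = nx.Graph()
    for i in heavy:
        pose_graph.add_node(i, element=pose.atoms[i].element)
    heavy_set = set(heavy)
    for i, j, _order in geo.bonds:
        if i in heavy_set and j in heavy_set:
            pose_graph.add_edge(i, j)

    matcher = nx.algorithms.isomorphism.GraphMatcher(
        template, pose_graph,
        node_match=lambda a, b: a["element"] == b["element"])
    try:
        mapping = next(matcher.isomorphisms_iter())
    except StopIteration:
        raise BondPerceptionError(
            f"{pose.source_path}: no heavy-atom mapping between pose geometry "
            f"and SMILES {smiles!r}") from None

    bonds: list[tuple[int, int, int]] = []
    for t_i, t_j, data in template.edges(data=True):
        bonds.append((mapping[t_i], mapping[t_j], data["order"]))
    # hydrogens retained in the pose keep geometric single bonds
    for i, j, order in geo.bonds:
        if i not in heavy_set or j not in heavy_set:
            bonds.append((i, j, order))
    return MolecularGraph(atoms=list(pose.atoms), bonds=bonds,
                          provenance="smiles_template")


def _heavy_elements(atoms: list[Atom]) -> Counter:
    return Counter(a.element for a in atoms if not a.is_hydrogen)


def bonds_from_external_tool(path: str | Path, tool_exec: str | Path,
                             timeout: float = 120.0) -> list[MolecularGraph]:
    """Assign bonds by converting a PDB/PDBQT file to SDF with Open Babel.

    Two attempts: first ``-h`` (add all hydrogens); if the converted heavy
    atoms do not match the input, retried with ``-p 7.4`` (protonate for
    neutral pH).  Both failing raises :class:`BondPerceptionError`, which
    the engine records as a skip — the run continues.
    """
    path = Path(path)
    from .structures import read_poses
    input_poses = read_poses(path)
    if not input_poses:
        raise BondPerceptionError(f"{path}: no poses to convert")
    want = _heavy_elements(input_poses[0].atoms)

    for attempt, extra in enumerate((["-h"], ["-p", "7.4"]), 1):
        with tempfile.TemporaryDirectory() as tmp:
            out_sdf = Path(tmp) / "converted.sdf"
            cmd = [str(tool_exec), str(path), "-O", str(out_sdf), *extra]
            try:
                proc = subprocess.run(cmd, capture_output=True, text=True,
                                      timeout=timeout)
            except (OSError, subprocess.TimeoutExpired) as exc:
                logger.warning("%s: conversion attempt %d failed to run: %s",
                               path, attempt, exc)
                continue
            if proc.returncode != 0 or not out_sdf.exists():
                logger.warning("%s: conversion attempt %d exited %d",
                               path, attempt, proc.returncode)
                continue
            try:
                sdf_poses = _read_sdf_poses(out_sdf.read_text(), str(out_sdf))
            except ValueError as exc:
                logger.warning("%s: attempt %d produced unparseable SDF: %s",
                               path, attempt, exc)
                continue
            if not sdf_poses:
                continue
            if _heavy_elements(sdf_poses[0].atoms) != want:
                logger.warning("%s: attempt %d heavy atoms do not match input; retrying",
                               path, attempt)
                continue
            graphs = [graph_from_sdf_pose(p) for p in sdf_poses]
            for g in graphs:
                g.provenance = "external_tool"
            return graphs
    raise BondPerceptionError(f"{path}: external bond assignment failed after 2 attempts")
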