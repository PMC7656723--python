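"""JSON filter files: parsing, validation, and query-point resolution.

A filter has four parts: a SMARTS substructure pattern, a 3D query point
(given directly as a coordinate or indirectly as a named receptor atom), a
distance cutoff in Å, and an optional exclude flag.  The JSON schema is::

    [
      {"smarts": "[#7,#8]",
       "receptorAtom": {"chain": "A", "resid": 863, "atomname": "CA"},
       "distance": 5.5},
      {"smarts": "cc",
       "coordinate": [12.0, -3.5, 7.1],
       "distance": 5.5,
       "exclude": true}
    ]

"Within the cutoff" is inclusive (<=).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem

from .structures import Receptor


class FilterSpecError(Exception):
    """Fatal problem in the filters file; named by filter index."""


_ALLOWED_KEYS = {"smarts", "coordinate", "receptorAtom", "distance", "exclude"}
_RECEPTOR_ATOM_KEYS = {"chain", "resid", "atomname"}


@dataclass(frozen=True)
class FilterDefinition:
    """One user filter as read from JSON, query point not yet resolved."""

    smarts: str
    cutoff: float
    exclude: bool = False
    coordinate: tuple[float, float, float] | None = None
    receptor_atom: tuple[str, int, str] | None = None  # (chain, resid, atomname)

    def __post_init__(self) -> None:
        if (self.coordinate is None) == (self.receptor_atom is None):
            raise FilterSpecError(
                "exactly one of 'coordinate' / 'receptorAtom' must be given")
        if not (self.cutoff > 0):
            raise FilterSpecError(f"distance cutoff must be > 0, got {self.cutoff}")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise FilterSpecError(f"invalid SMARTS pattern: {self.smarts!r}")

    def to_json_obj(self) -> dict:
        obj: dict = {"smarts": self.smarts, "distance": self.cutoff}
        if self.coordinate is not None:
            obj["coordinate"] = list(self.coordinate)
        else:
            chain, resid, atomname = self.receptor_atom
            obj["receptorAtom"] = {"chain": chain, "resid": resid,
                                   "atomname": atomname}
        if self.exclude:
            obj["exclude"] = True
        return obj


@dataclass(frozen=True)
class ResolvedFilter:
    """A filter with a concrete 3D query point, ready to evaluate."""

    smarts: str
    query_point: tuple[float, float, float]
    cutoff: float
    exclude: bool
    label: str

    def __post_init__(self) -> None:
        if len(self.query_point) != 3 or not all(math.isfinite(c) for c in self.query_point):
            raise FilterSpecError(f"{self.label}: query point must be 3 finite numbers")

    @property
    def pattern(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.smarts)


def _parse_one(obj: dict, index: int) -> FilterDefinition:
    where = f"filter #{index}"
    if not isinstance(obj, dict):
        raise FilterSpecError(f"{where}: each filter must be a JSON object")
    unknown = set(obj) - _ALLOWED_KEYS
    if unknown:
        raise FilterSpecError(f"{where}: unknown key(s) {sorted(unknown)}")
    for req in ("smarts", "distance"):
        if req not in obj:
            raise FilterSpecError(f"{where}: missing required key {req!r}")
    coordinate = None
    receptor_atom = None
    if "coordinate" in obj and "receptorAtom" in obj:
        raise FilterSpecError(f"{where}: give either 'coordinate' or 'receptorAtom', not both")
    if "coordinate" in obj:
        coord = obj["coordinate"]
        if not (isinstance(coord, (list, tuple)) and len(coord) == 3):
            raise FilterSpecError(f"{where}: 'coordinate' must be a list of 3 numbers")
        coordinate = tuple(float(c) for c in coord)
    elif "receptorAtom" in obj:
        ra = obj["receptorAtom"]
        if not isinstance(ra, dict) or set(ra) != _RECEPTOR_ATOM_KEYS:
            raise FilterSpecError(
                f"{where}: 'receptorAtom' needs exactly keys "
                f"{sorted(_RECEPTOR_ATOM_KEYS)}")
        receptor_atom = (str(ra["chain"]), int(ra["resid"]), str(ra["atomname"]))
    else:
        raise FilterSpecError(f"{where}: one of 'coordinate'/'receptorAtom' is required")
    try:
        return FilterDefinition(
            smarts=str(obj["smarts"]),
            cutoff=float(obj["distance"]),
            exclude=bool(obj.get("exclude", False)),
            coordinate=coordinate,
            receptor_atom=receptor_atom,
        )
    except FilterSpecError as exc:
        raise FilterSpecError(f"{where}: {exc}") from None


def load_filters(path: str | Path) -> list[FilterDefinition]:
    """Load the filters file; order is preserved.

    An empty list is legal (vacuous conjunction: every parseable compound
    passes), which is handy for smoke-testing a pipeline.
    """
    try:
        data = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FilterSpecError(f"cannot read filters file {path}: {exc}") from exc
    if not isinstance(data, list):
        raise FilterSpecError("filters file must contain a JSON list")
    return [_parse_one(obj, i) for i, obj in enumerate(data)]


def dump_filters(filters: list[FilterDefinition], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([f.to_json_obj() for f in filters], indent=2) + "\n")


def resolve_query_point(f: FilterDefinition,
                        receptor: Receptor | None = None) -> ResolvedFilter:
    """Turn a filter definition into one with a concrete 3D point.

    A receptorAtom selector that does not resolve aborts before any pose is
    evaluated (error propagated from the receptor lookup).
    """
    if f.coordinate is not None:
        point = f.coordinate
        label = f"{f.smarts} @ coordinate {list(point)}"
    else:
        chain, resid, atomname = f.receptor_atom
        if receptor is None:
            raise FilterSpecError(
                f"filter {f.smarts!r} uses receptorAtom but no receptor was given")
        atom = receptor.select_atom(chain, resid, atomname)
        point = atom.coords
        label = f"{f.smarts} @ {chain}:{resid}:{atomname}"
    label += f" <= {f.cutoff} Å" + (" (exclude)" if f.exclude else "")
    return ResolvedFilter(smarts=f.smarts, query_point=tuple(point),
                          cutoff=f.cutoff, exclude=f.exclude, label=label)


def _smarts_needs_bond_orders(smarts: str) -> bool:
    """True when the pattern can only match with non-single/aromatic bonds or
    aromatic atoms — i.e. it can never hit a single-bond-only graph."""
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        return False
    for atom in patt.GetAtoms():
        if atom.GetIsAromatic():
            return True
    for bond in patt.GetBonds():
        if bond.GetBondType() in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE,
                                  Chem.BondType.AROMATIC):
            return True
        if bond.GetIsAromatic():
            return True
    return False


def validate_smarts_for_mode(f: FilterDefinition, mode: str,
                             formats_present: set[str]) -> list[str]:
    """Advisory checks on filter/mode/format combinations (warnings only).

    NONE-mode graphs for PDB/PDBQT poses contain only single bonds between
    sp3-treated atoms, so a SMARTS needing aromatic or higher-order bonds
    can never match there.  SMILES/OPENBABEL modes are redundant for SDF
    input, which already carries bond orders.
    """
    warnings: list[str] = []
    pdbish = bool(formats_present & {"PDB", "PDBQT"})
    if mode == "NONE" and pdbish and _smarts_needs_bond_orders(f.smarts):
        warnings.append(
            f"SMARTS {f.smarts!r} requires aromatic/higher-order bonds, which NONE "
            f"mode never assigns to PDB/PDBQT poses; this filter cannot match them")
    if mode in ("SMILES", "OPENBABEL") and "SDF" in formats_present:
        warnings.append(
            f"{mode} mode is unnecessary for SDF files, which already include "
            f"bond-order information; their own bond blocks will be used")
    return warnings
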