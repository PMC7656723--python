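"""The pose-screening engine.

Every pose of every docked-compound file is tested against every resolved
filter; a compound file passes when at least one of its poses satisfies all
filters (Boolean AND across filters, OR across poses).  Passing file names
are written one per line in lexicographic order, so screening a library is
reproducible byte-for-byte regardless of directory enumeration order or
worker count.

Per-filter pass/fail semantics
------------------------------

===================  ============  ======================  ======
has substructure     exclude set   any atom within cutoff  result
===================  ============  ======================  ======
no                   no            n/a                     Fail
no                   yes           n/a                     Pass
yes                  no            no                      Fail
yes                  no            yes                     Pass
yes                  yes           no                      Pass
yes                  yes           yes                     Fail
===================  ============  ======================  ======

Errors confined to one compound file (unparseable input, failed bond
assignment) are recorded as skips and the run continues; only receptor or
filter problems are fatal.
"""

from __future__ import annotations

import csv
import logging
import math
import multiprocessing
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .bonds import (
    BondPerceptionError, CovalentRadiusTable, MolecularGraph,
    bonds_from_external_tool, bonds_from_smiles_template, graph_from_sdf_pose,
    infer_bonds_geometric,
)
from .filters import (
    FilterDefinition, ResolvedFilter, load_filters, resolve_query_point,
    validate_smarts_for_mode,
)
from .structures import (
    PoseRecord, discover_compound_files, read_poses, read_receptor,
    smiles_companion,
)

logger = logging.getLogger("posegrep")

MODES = ("NONE", "SMILES", "OPENBABEL")


@dataclass(frozen=True)
class FilterVerdict:
    filter_label: str
    has_substructure: bool
    within_cutoff: bool | None  # None = not applicable (no substructure)
    passed: bool
    min_distance: float | None  # Å; None when no substructure


@dataclass
class ScreenResult:
    """Per-compound verdicts for one screening run."""

    passes: dict[str, list[int]] = field(default_factory=dict)  # file -> pose indices
    failures: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (file, reason)
    warnings: list[str] = field(default_factory=list)
    details: list[dict] = field(default_factory=list)  # verbose sidecar rows

    @property
    def n_seen(self) -> int:
        return len(self.passes) + len(self.failures) + len(self.skipped)

    def passing_files(self) -> list[str]:
        return sorted(self.passes)

    def write_output(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(name + "\n" for name in self.passing_files()))

    def write_sidecar(self, path: str | Path) -> None:
        """TSV of per-pose, per-filter evaluations (additive diagnostics)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["file", "pose_index", "filter_label",
                        "min_distance_A", "verdict"])
            for row in self.details:
                w.writerow([row["file"], row["pose_index"], row["filter_label"],
                            "" if row["min_distance"] is None
                            else f"{row['min_distance']:.3f}",
                            "pass" if row["passed"] else "fail"])


def match_substructure(graph: MolecularGraph, smarts: str | Chem.Mol) -> list[tuple[int, ...]]:
    """All embeddings of a SMARTS pattern in the graph, as atom-index tuples."""
    patt = Chem.MolFromSmarts(smarts) if isinstance(smarts, str) else smarts
    if patt is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    mol = graph.to_rdkit()
    return [tuple(m) for m in mol.GetSubstructMatches(patt, uniquify=True,
                                                      maxMatches=100000)]


def min_distance(atom_sets: list[tuple[int, ...]], graph: MolecularGraph,
                 query_point) -> float:
    """Minimum Euclidean distance from the query point to any atom in any
    embedding of the substructure."""
    if not atom_sets:
        raise ValueError("atom_sets must be non-empty")
    indices = sorted({i for s in atom_sets for i in s})
    coords = graph.coords_array()[indices]
    q = np.asarray(query_point, dtype=float)
    return float(np.min(np.linalg.norm(coords - q, axis=1)))


def evaluate_filter(pose_graph: MolecularGraph, f: ResolvedFilter,
                    _mol: Chem.Mol | None = None) -> FilterVerdict:
    """Evaluate one filter on one pose graph (truth table in module docs).

    "Within cutoff" is inclusive (distance <= cutoff).
    """
    patt = _mol if _mol is not None else Chem.MolFromSmarts(f.smarts)
    matches = match_substructure(pose_graph, patt)
    if not matches:
        return FilterVerdict(filter_label=f.label, has_substructure=False,
                             within_cutoff=None, passed=f.exclude,
                             min_distance=None)
    d = min_distance(matches, pose_graph, f.query_point)
    within = d <= f.cutoff
    return FilterVerdict(filter_label=f.label, has_substructure=True,
                         within_cutoff=within, passed=(within != f.exclude),
                         min_distance=d)


def evaluate_pose(pose_graph: MolecularGraph,
                  filters: list[ResolvedFilter]) -> tuple[bool, list[FilterVerdict]]:
    """Conjunction over all filters; empty filter list is vacuously true."""
    verdicts = [evaluate_filter(pose_graph, f) for f in filters]
    return all(v.passed for v in verdicts), verdicts


def _graphs_for_file(path: Path, poses: list[PoseRecord], mode: str,
                     radii: CovalentRadiusTable | None,
                     babel_exec: str | None,
                     warnings: list[str]) -> list[tuple[PoseRecord, MolecularGraph]]:
    """Assign bond graphs to every pose of one file according to the mode.

    SDF poses always use their own bond block.  In SMILES mode the
    template mapping is computed once for the first pose and its bond list
    reused for the rest: Vina MODEL blocks are conformers of one molecule
    with a shared atom order.
    """
    if poses and poses[0].format == "SDF":
        return [(p, graph_from_sdf_pose(p)) for p in poses]

    if mode == "NONE":
        return [(p, infer_bonds_geometric(p, radii)) for p in poses]

    if mode == "SMILES":
        smi_path = smiles_companion(path)
        if smi_path is None:
            warnings.append(f"{path.name}: no .smi companion; using NONE-mode bonds")
            return [(p, infer_bonds_geometric(p, radii)) for p in poses]
        smiles = smi_path.read_text().split()[0] if smi_path.read_text().strip() else ""
        try:
            first = bonds_from_smiles_template(poses[0], smiles, radii)
        except BondPerceptionError as exc:
            warnings.append(f"{path.name}: {exc}; using NONE-mode bonds")
            return [(p, infer_bonds_geometric(p, radii)) for p in poses]
        out = [(poses[0], first)]
        for p in poses[1:]:
            if len(p.atoms) == len(first.atoms):
                out.append((p, MolecularGraph(atoms=list(p.atoms),
                                              bonds=list(first.bonds),
                                              provenance="smiles_template")))
            else:  # atom count drifted between MODEL blocks; remap from scratch
                try:
                    out.append((p, bonds_from_smiles_template(p, smiles, radii)))
                except BondPerceptionError as exc:
                    warnings.append(f"{path.name} pose {p.pose_index}: {exc}; "
                                    f"using NONE-mode bonds")
                    out.append((p, infer_bonds_geometric(p, radii)))
        return out

    if mode == "OPENBABEL":
        if babel_exec is None:
            raise ValueError("OPENBABEL mode requires babel_exec")
        graphs = bonds_from_external_tool(path, babel_exec)
        if len(graphs) != len(poses):
            raise BondPerceptionError(
                f"{path.name}: converter returned {len(graphs)} poses for "
                f"{len(poses)} input poses")
        return list(zip(poses, graphs))

    raise ValueError(f"unknown mode {mode!r}")


def _evaluate_file(args) -> dict:
    """Worker: evaluate one compound file. Top-level for pickling."""
    path_str, filters, mode, radii, babel_exec = args
    path = Path(path_str)
    out: dict = {"file": path.name, "status": None, "pose_passes": [],
                 "warnings": [], "details": [], "reason": ""}
    try:
        poses = read_poses(path)
    except Exception as exc:  # unparseable file: skip, never fatal
        out["status"] = "skipped"
        out["reason"] = f"unparseable: {exc}"
        return out
    if not poses:
        out["status"] = "skipped"
        out["reason"] = "no poses found in file"
        return out
    try:
        pose_graphs = _graphs_for_file(path, poses, mode, radii, babel_exec,
                                       out["warnings"])
    except (BondPerceptionError, ValueError) as exc:
        out["status"] = "skipped"
        out["reason"] = str(exc)
        return out
    for pose, graph in pose_graphs:
        ok, verdicts = evaluate_pose(graph, filters)
        if ok:
            out["pose_passes"].append(pose.pose_index)
        for v in verdicts:
            out["details"].append({
                "file": path.name, "pose_index": pose.pose_index,
                "filter_label": v.filter_label,
                "min_distance": v.min_distance, "passed": v.passed,
            })
    out["status"] = "passed" if out["pose_passes"] else "failed"
    return out


def run_screen(receptor_path: str | Path | None,
               compounds_dir: str | Path,
               filters_path: str | Path,
               mode: str = "NONE",
               babel_exec: str | None = None,
               radii: CovalentRadiusTable | None = None,
               jobs: int = 1) -> ScreenResult:
    """Screen a directory of docked-compound files against a filters file.

    ``receptor_path`` may be None when every filter uses a literal
    coordinate.  Work units are whole compound files; results are merged in
    lexicographic file order, so the outcome is identical for any ``jobs``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    definitions = load_filters(filters_path)
    receptor = read_receptor(receptor_path) if receptor_path is not None else None
    filters = [resolve_query_point(d, receptor) for d in definitions]

    files = discover_compound_files(compounds_dir)
    formats_present = {f.suffix.lower().lstrip(".").upper() for f in files}
    result = ScreenResult()
    for d in definitions:
        for w in validate_smarts_for_mode(d, mode, formats_present):
            logger.warning(w)
            result.warnings.append(w)

    tasks = [(str(f), filters, mode, radii, babel_exec) for f in files]
    if jobs > 1 and len(tasks) > 1 and sys.platform != "win32":
        with multiprocessing.Pool(jobs) as pool:
            raw = pool.map(_evaluate_file, tasks)
    else:
        raw = [_evaluate_file(t) for t in tasks]

    for rec in sorted(raw, key=lambda r: r["file"]):
        result.warnings.extend(rec["warnings"])
        for w in rec["warnings"]:
            logger.warning(w)
        if rec["status"] == "skipped":
            result.skipped.append((rec["file"], rec["reason"]))
            logger.warning("skipping %s: %s", rec["file"], rec["reason"])
        elif rec["status"] == "passed":
            result.passes[rec["file"]] = rec["pose_passes"]
        else:
            result.failures.append(rec["file"])
        result.details.extend(rec["details"])
    return result
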