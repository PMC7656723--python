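"""Deterministic synthetic inputs with known ground truth.

Everything the rest of the package consumes — receptor structures, docked
poses in PDBQT/PDB/SDF, SMILES companions, filter files, ranked libraries —
can be generated here from a seed, with a truth table recording which
compounds (and which pose indices) were built to pass.  Molecules are
assembled from a small library of rigid fragment templates with near-ideal
bond lengths, so geometric bond inference is unambiguous; fragments carrying
a filter's substructure are placed inside or outside the cutoff sphere by
construction, and jitter is clipped so no atom sits within 0.2 Å of a
pass/fail boundary.

These fixtures emulate the *geometry* of a docking run (multiple poses per
compound, polar-heavy-atom PDBQT content, pre-aligned frames).  They do not
emulate chemistry (strain, valence realism) or any docking score model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bonds import MolecularGraph
from .engine import match_substructure, min_distance
from .filters import FilterDefinition, ResolvedFilter, dump_filters, resolve_query_point
from .metrics import RankedEntry, RankedLibrary
from .structures import Atom, PoseRecord, Receptor, write_poses, write_receptor

MAX_POSES_PER_COMPOUND = 18  # docking-protocol ceiling: 2 variants x 9 poses
BOUNDARY_MARGIN = 0.2  # no fixture atom may sit this close to a cutoff sphere


class FixtureError(Exception):
    pass


# --------------------------------------------------------------------------
# Rigid fragment templates (heavy atoms only, near-ideal bond lengths)

@dataclass(frozen=True)
class FragmentTemplate:
    name: str
    smiles: str
    elements: tuple[str, ...]
    coords: tuple[tuple[float, float, float], ...]
    bonds: tuple[tuple[int, int, int], ...]  # (i, j, order)

    def radius(self) -> float:
        c = np.asarray(self.coords)
        return float(np.max(np.linalg.norm(c - c.mean(axis=0), axis=1)))


def _hexagon(r: float) -> list[tuple[float, float, float]]:
    return [(r * math.cos(k * math.pi / 3), r * math.sin(k * math.pi / 3), 0.0)
            for k in range(6)]


_ZIG_DX, _ZIG_DY = 1.257, 0.889  # 1.54 Å bonds at tetrahedral angles

FRAGMENTS: dict[str, FragmentTemplate] = {
    "ethanol": FragmentTemplate(
        name="ethanol", smiles="CCO",
        elements=("C", "C", "O"),
        coords=((0.0, 0.0, 0.0), (1.54, 0.0, 0.0), (2.017, 1.348, 0.0)),
        bonds=((0, 1, 1), (1, 2, 1)),
    ),
    "methylamine": FragmentTemplate(
        name="methylamine", smiles="CN",
        elements=("C", "N"),
        coords=((0.0, 0.0, 0.0), (1.47, 0.0, 0.0)),
        bonds=((0, 1, 1),),
    ),
    "benzene": FragmentTemplate(
        name="benzene", smiles="c1ccccc1",
        elements=("C",) * 6,
        coords=tuple(_hexagon(1.39)),
        bonds=tuple((k, (k + 1) % 6, 4) for k in range(6)),
    ),
    "thp": FragmentTemplate(  # tetrahydro-2H-pyran
        name="thp", smiles="C1OCCCC1",
        elements=("C", "O", "C", "C", "C", "C"),
        coords=tuple(_hexagon(1.48)),
        bonds=tuple((k, (k + 1) % 6, 1) for k in range(6)),
    ),
    "butane": FragmentTemplate(
        name="butane", smiles="CCCC",
        elements=("C",) * 4,
        coords=((0.0, 0.0, 0.0), (_ZIG_DX, _ZIG_DY, 0.0),
                (2 * _ZIG_DX, 0.0, 0.0), (3 * _ZIG_DX, _ZIG_DY, 0.0)),
        bonds=((0, 1, 1), (1, 2, 1), (2, 3, 1)),
    ),
}

# Single-bond-only fragments are safe under geometric (NONE-mode) perception.
SINGLE_BOND_FRAGMENTS = ("ethanol", "methylamine", "thp", "butane")


def _fragment_graph(frag: FragmentTemplate) -> MolecularGraph:
    atoms = [Atom(serial=i + 1, name=f"{el}{i + 1}", element=el, coords=xyz,
                  resname="LIG", resid=1)
             for i, (el, xyz) in enumerate(zip(frag.elements, frag.coords))]
    return MolecularGraph(atoms=atoms, bonds=list(frag.bonds),
                          provenance="sdf_block")


def fragment_matches(frag: FragmentTemplate, smarts: str) -> list[tuple[int, ...]]:
    """Which atoms of a fragment embed the SMARTS (orders as authored)."""
    return match_substructure(_fragment_graph(frag), smarts)


# --------------------------------------------------------------------------
# Receptor fixtures

DEFAULT_ANCHORS: tuple[tuple[str, int, str, str, tuple[float, float, float]], ...] = (
    # (chain, resid, atomname, resname, coords) — glycine-863 backbone plus a
    # distal tyrosine-907 ring carbon, echoing hydrogen-bond / pi-stacking
    # anchor atoms a structure-based filter would use.
    ("A", 863, "N", "GLY", (-1.46, 0.0, 0.0)),
    ("A", 863, "CA", "GLY", (0.0, 0.0, 0.0)),
    ("A", 863, "C", "GLY", (0.55, 1.44, 0.0)),
    ("A", 863, "O", "GLY", (1.77, 1.62, 0.0)),
    ("A", 907, "CZ", "TYR", (14.0, 2.0, 1.0)),
    ("A", 907, "OH", "TYR", (15.37, 2.0, 1.0)),
)


def make_receptor_fixture(path: str | Path, fmt: str = "PDB",
                          anchors=DEFAULT_ANCHORS,
                          extra_chain: str | None = None) -> Receptor:
    """Write a small receptor whose named anchor atoms sit at known coordinates.

    Duplicate (chain, resid, atomname) triples are refused, mirroring the
    loader's uniqueness invariant.
    """
    triples = [(c, r, n) for c, r, n, _rn, _x in anchors]
    if len(set(triples)) != len(triples):
        raise FixtureError("duplicate (chain, resid, atomname) triple in anchor spec")
    atoms = [Atom(serial=i + 1, name=name, element=name[0], coords=xyz,
                  chain=chain, resid=resid, resname=resname)
             for i, (chain, resid, name, resname, xyz) in enumerate(anchors)]
    if extra_chain:
        base = len(atoms)
        atoms.append(Atom(serial=base + 1, name="CA", element="C",
                          coords=(-20.0, -20.0, -20.0), chain=extra_chain,
                          resid=1, resname="ALA"))
    write_receptor(atoms, path, fmt=fmt)
    return Receptor(atoms=atoms, source_path=str(path), format=fmt)


def default_filters(single_bond_only: bool = True) -> list[FilterDefinition]:
    """Filters in the style of structure-based screening campaigns.

    The default asks for a ligand N or O within 5.5 Å of the Gly-863 alpha
    carbon (a hydrogen-bond surrogate).  With ``single_bond_only=False`` an
    aromatic C–C bond near the Tyr-907 CZ atom (a pi-stacking surrogate) is
    added; that one needs real bond orders, so NONE mode on PDB/PDBQT input
    can never satisfy it.
    """
    filters = [FilterDefinition(
        smarts="[#7,#8]", cutoff=5.5,
        receptor_atom=("A", 863, "CA"))]
    if not single_bond_only:
        filters.append(FilterDefinition(
            smarts="cc", cutoff=5.5,
            receptor_atom=("A", 907, "CZ")))
    return filters


# --------------------------------------------------------------------------
# Pose fixtures

@dataclass
class FixtureSpec:
    seed: int = 7
    n_compounds: int = 100
    poses_per_compound: int = 3
    fraction_designed_to_pass: float = 0.4
    formats: tuple[str, ...] = ("PDBQT", "PDB", "SDF")
    geometry_noise: float = 0.05  # Å sd of clipped per-atom jitter
    corrupt_fraction: float = 0.0  # salt the directory with unparseable files

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_designed_to_pass <= 1.0):
            raise FixtureError("fraction_designed_to_pass must be in [0, 1]")
        if not (1 <= self.poses_per_compound <= MAX_POSES_PER_COMPOUND):
            raise FixtureError(
                f"poses_per_compound must be in [1, {MAX_POSES_PER_COMPOUND}]")
        if any(f not in ("PDBQT", "PDB", "SDF") for f in self.formats):
            raise FixtureError(f"unknown format in {self.formats}")


@dataclass
class GroundTruth:
    """file name -> (expected verdict, expected passing pose indices)."""

    expected: dict[str, tuple[bool, tuple[int, ...]]] = field(default_factory=dict)
    corrupt_files: list[str] = field(default_factory=list)

    def passing_files(self) -> list[str]:
        return sorted(f for f, (ok, _p) in self.expected.items() if ok)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["file\texpected_pass\tpassing_pose_indices"]
        for name in sorted(self.expected):
            ok, poses = self.expected[name]
            lines.append(f"{name}\t{int(ok)}\t{','.join(map(str, poses))}")
        Path(path).write_text("\n".join(lines) + "\n")


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a uniform random rotation
    m, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(m) < 0:
        m[:, 0] = -m[:, 0]
    return m


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _place_fragment(frag: FragmentTemplate, rng: np.random.Generator,
                    anchor_local: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigidly rotate the fragment and translate so ``anchor_local`` (a point
    in fragment coordinates) lands on ``target``."""
    rot = _rotation_matrix(rng)
    coords = np.asarray(frag.coords) @ rot.T
    anchor = anchor_local @ rot.T
    return coords + (target - anchor)


def _choose_fragment_for(smarts: str, rng: np.random.Generator,
                         single_bond_only: bool) -> tuple[FragmentTemplate, list[tuple[int, ...]]]:
    pool = SINGLE_BOND_FRAGMENTS if single_bond_only else tuple(FRAGMENTS)
    candidates = []
    for name in pool:
        frag = FRAGMENTS[name]
        m = fragment_matches(frag, smarts)
        if m:
            candidates.append((frag, m))
    if not candidates:
        raise FixtureError(f"no fragment template contains substructure {smarts!r}")
    return candidates[rng.integers(len(candidates))]


def _brute_force_verdict(elements: list[str], coords: np.ndarray,
                         bonds: list[tuple[int, int, int]],
                         filters: list[ResolvedFilter]) -> tuple[bool, list[float | None]]:
    """Verify a constructed pose against the truth table, with margins."""
    graph = MolecularGraph(
        atoms=[Atom(serial=i + 1, name=f"{el}{i + 1}", element=el,
                    coords=tuple(xyz), resname="LIG", resid=1)
               for i, (el, xyz) in enumerate(zip(elements, coords))],
        bonds=bonds, provenance="sdf_block")
    dists: list[float | None] = []
    ok = True
    for f in filters:
        matches = match_substructure(graph, f.smarts)
        if not matches:
            dists.append(None)
            ok = ok and f.exclude
            continue
        d = min_distance(matches, graph, f.query_point)
        dists.append(d)
        if abs(d - f.cutoff) < BOUNDARY_MARGIN:
            raise FixtureError(
                f"construction placed an atom {d:.2f} Å from a {f.cutoff} Å "
                f"cutoff, inside the {BOUNDARY_MARGIN} Å safety margin")
        ok = ok and ((d <= f.cutoff) != f.exclude)
    return ok, dists


def _build_pose(rng: np.random.Generator, filters: list[ResolvedFilter],
                frag_for_filter: list[tuple[FragmentTemplate, list[tuple[int, ...]]] | None],
                extra_frags: list[FragmentTemplate],
                should_pass: bool, violated: int | None,
                noise: float) -> tuple[list[str], np.ndarray, list[tuple[int, int, int]], list[str]]:
    """Assemble one pose. Returns (elements, coords, bonds, fragment SMILES)."""
    qpoints = [np.asarray(f.query_point) for f in filters]
    center = np.mean(qpoints, axis=0) if qpoints else np.zeros(3)
    max_cut = max((f.cutoff for f in filters), default=5.0)

    def remote_target() -> np.ndarray:
        return center + _random_unit(rng) * (max_cut + 22.0 + rng.uniform(0, 6))

    pieces: list[tuple[FragmentTemplate, np.ndarray]] = []
    for k, f in enumerate(filters):
        entry = frag_for_filter[k]
        if entry is None:  # exclude filter: no dedicated fragment
            continue
        frag, matches = entry
        anchor_idx = matches[0][0]
        anchor_local = np.asarray(frag.coords[anchor_idx])
        inside = (not f.exclude) and should_pass and (violated != k)
        if f.exclude and violated == k:
            inside = True  # deliberate violation of an exclusion sphere
        if inside:
            lo = max(1.2, f.cutoff * 0.25)
            hi = f.cutoff - (BOUNDARY_MARGIN + 0.4)
            if hi <= lo:
                raise FixtureError(
                    f"cutoff {f.cutoff} Å too small to place a fragment inside")
            target = np.asarray(f.query_point) + _random_unit(rng) * rng.uniform(lo, hi)
        else:
            target = remote_target()
        pieces.append((frag, _place_fragment(frag, rng, anchor_local, target)))
    if not pieces and not extra_frags:
        extra_frags = [FRAGMENTS["butane"]]  # a molecule must have atoms
    for frag in extra_frags:
        rot = _rotation_matrix(rng)
        pieces.append((frag, np.asarray(frag.coords) @ rot.T + remote_target()))

    # keep fragments from fusing: nudge any pair closer than 4 Å apart
    for _attempt in range(50):
        moved = False
        for a in range(len(pieces)):
            for b in range(a + 1, len(pieces)):
                ca, cb = pieces[a][1], pieces[b][1]
                d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2).min()
                if d < 4.0:
                    shift = _random_unit(rng) * (4.5 - d)
                    pieces[b] = (pieces[b][0], cb + shift)
                    moved = True
        if not moved:
            break

    elements: list[str] = []
    coords_parts: list[np.ndarray] = []
    bonds: list[tuple[int, int, int]] = []
    smiles_parts: list[str] = []
    offset = 0
    for frag, coords in pieces:
        elements.extend(frag.elements)
        coords_parts.append(coords)
        bonds.extend((i + offset, j + offset, order) for i, j, order in frag.bonds)
        smiles_parts.append(frag.smiles)
        offset += len(frag.elements)
    all_coords = np.vstack(coords_parts)
    if noise > 0:
        jitter = np.clip(rng.normal(scale=noise, size=all_coords.shape), -0.1, 0.1)
        all_coords = all_coords + jitter
    return elements, all_coords, bonds, smiles_parts


def make_pose_fixtures(spec: FixtureSpec, out_dir: str | Path,
                       filters: list[ResolvedFilter],
                       single_bond_only: bool = True) -> GroundTruth:
    """Write a directory of docked-compound files with a known truth table.

    Each compound is assembled from fragment templates so that each filter's
    substructure sits inside or outside its cutoff sphere by construction;
    every constructed pose is re-verified with a direct distance/match check
    before being written.  Designed-to-pass compounds get a random non-empty
    subset of passing poses, so some files pass only through a non-top pose.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    n_pass = round(spec.fraction_designed_to_pass * spec.n_compounds)
    verdicts = np.zeros(spec.n_compounds, dtype=bool)
    verdicts[:n_pass] = True
    rng.shuffle(verdicts)

    non_exclude = [k for k, f in enumerate(filters) if not f.exclude]
    exclude_idx = [k for k, f in enumerate(filters) if f.exclude]
    truth = GroundTruth()

    for c in range(spec.n_compounds):
        fmt = spec.formats[c % len(spec.formats)]
        name = f"cmpd_{c:04d}.{fmt.lower()}"
        should_pass = bool(verdicts[c])

        frag_for_filter: list = []
        for k, f in enumerate(filters):
            if f.exclude:
                frag_for_filter.append(
                    _choose_fragment_for(f.smarts, rng, single_bond_only)
                    if (not should_pass and exclude_idx and k == exclude_idx[0]
                        and not non_exclude)
                    else None)
            else:
                frag_for_filter.append(
                    _choose_fragment_for(f.smarts, rng, single_bond_only))
        extras = [FRAGMENTS["butane"]] if rng.random() < 0.3 else []

        if should_pass:
            mask = rng.random(spec.poses_per_compound) < 0.5
            if not mask.any():
                mask[rng.integers(spec.poses_per_compound)] = True
            pass_poses = [i + 1 for i, m in enumerate(mask) if m]
        else:
            pass_poses = []
        # which filter a failing pose violates
        if non_exclude:
            violated_filter = int(rng.choice(non_exclude))
        elif exclude_idx:
            violated_filter = exclude_idx[0]
        else:
            raise FixtureError("cannot design failing compounds with no filters")

        poses: list[PoseRecord] = []
        smiles_parts_first: list[str] = []
        for p in range(1, spec.poses_per_compound + 1):
            pose_passes = p in pass_poses
            for _retry in range(20):
                elements, coords, bonds, smiles_parts = _build_pose(
                    rng, filters, frag_for_filter, extras,
                    should_pass=pose_passes,
                    violated=None if pose_passes else violated_filter,
                    noise=spec.geometry_noise)
                actual, _d = _brute_force_verdict(elements, coords, bonds, filters)
                if actual == pose_passes:
                    break
            else:
                raise FixtureError(
                    f"could not realize designed verdict for {name} pose {p}")
            atoms = [Atom(serial=i + 1, name=f"{el}{i + 1}", element=el,
                          coords=tuple(np.round(xyz, 3)), resname="LIG", resid=1)
                     for i, (el, xyz) in enumerate(zip(elements, coords))]
            poses.append(PoseRecord(atoms=atoms, bonds=list(bonds), pose_index=p,
                                    source_path=name, format=fmt,
                                    title=Path(name).stem))
            if p == 1:
                smiles_parts_first = smiles_parts

        write_poses(poses, out_dir / name, fmt=fmt)
        if fmt in ("PDB", "PDBQT"):
            (out_dir / (name + ".smi")).write_text(
                ".".join(smiles_parts_first) + "\n")
        truth.expected[name] = (should_pass, tuple(pass_poses))

    if spec.corrupt_fraction > 0:
        n_corrupt = max(1, round(spec.corrupt_fraction * spec.n_compounds))
        for c in range(n_corrupt):
            name = f"corrupt_{c:03d}.sdf"
            (out_dir / name).write_text(
                "broken\n  posegrep\n\nxxx garbage counts line V2000\n$$$$\n")
            truth.corrupt_files.append(name)
    return truth


def make_screen_fixture(out_dir: str | Path, spec: FixtureSpec | None = None,
                        filters: list[FilterDefinition] | None = None,
                        single_bond_only: bool = True,
                        receptor_fmt: str = "PDB"):
    """One-call fixture: receptor + filters JSON + pose directory + truth TSV.

    Returns (receptor_path, compounds_dir, filters_path, truth).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or FixtureSpec()
    filters = filters if filters is not None else default_filters(single_bond_only)

    receptor_path = out_dir / f"receptor.{receptor_fmt.lower()}"
    receptor = make_receptor_fixture(receptor_path, fmt=receptor_fmt)
    filters_path = out_dir / "filters.json"
    dump_filters(filters, filters_path)
    resolved = [resolve_query_point(f, receptor) for f in filters]

    compounds_dir = out_dir / "compounds"
    truth = make_pose_fixtures(spec, compounds_dir, resolved,
                               single_bond_only=single_bond_only)
    truth.write_tsv(out_dir / "ground_truth.tsv")
    return receptor_path, compounds_dir, filters_path, truth


# --------------------------------------------------------------------------
# Ranked-library fixtures

def make_ranked_library_fixture(seed: int, T: int, P_T: int,
                                placement: str | list[int] = "uniform",
                                rescue: bool = False) -> RankedLibrary:
    """Deterministic labelled ranking for the metrics module.

    ``placement`` is either an explicit list of 1-based ranks for the
    positives or ``"uniform"`` (random ranks from the seed).  With
    ``rescue=True`` the fixture marks high-ranking decoys as filter
    failures and keeps positives passing, so filtering is guaranteed to
    raise early enrichment.  Sizes default in tests to the scale of a
    screen of ~1561 compounds with 46 knowns.
    """
    if P_T > T:
        raise ValueError("P_T cannot exceed T")
    rng = np.random.default_rng(seed)
    if isinstance(placement, str):
        if placement != "uniform":
            raise ValueError(f"unknown placement {placement!r}")
        ranks = set(map(int, rng.choice(T, size=P_T, replace=False) + 1))
    else:
        if len(placement) != P_T or max(placement) > T or min(placement) < 1:
            raise ValueError("placement ranks must be P_T distinct values in [1, T]")
        ranks = set(placement)
    entries = []
    for r in range(1, T + 1):
        positive = r in ranks
        passed = True
        if rescue and not positive and r <= 40:
            passed = False  # high-scoring decoy with implausible poses
        entries.append(RankedEntry(
            compound_id=f"cmpd_{r:05d}", score=-15.0 + 0.01 * r,
            is_positive=positive, passed_filters=passed))
    return RankedLibrary.from_entries(entries)
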