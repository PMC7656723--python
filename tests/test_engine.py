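"""Screening engine: substructure matching, distances, verdicts, full runs."""

import numpy as np
import pytest

from posegrep.bonds import MolecularGraph, infer_bonds_geometric
from posegrep.engine import (
    evaluate_filter, evaluate_pose, match_substructure, min_distance, run_screen,
)
from posegrep.filters import FilterDefinition, resolve_query_point
from posegrep.fixtures import FRAGMENTS
from posegrep.structures import Atom, PoseRecord


def _graph(spec, bonds, provenance="sdf_block"):
    atoms = [Atom(serial=i + 1, name=f"{el}{i+1}", element=el,
                  coords=tuple(xyz), resname="LIG", resid=1)
             for i, (el, xyz) in enumerate(spec)]
    return MolecularGraph(atoms=atoms, bonds=bonds, provenance=provenance)


def _filter(smarts, cutoff, point=(0.0, 0.0, 0.0), exclude=False):
    return resolve_query_point(FilterDefinition(
        smarts=smarts, cutoff=cutoff, coordinate=tuple(point), exclude=exclude))


class TestMatchSubstructure:
    def test_nitrogen_or_oxygen_matches_each_heteroatom(self):
        g = _graph([("N", (0, 0, 0)), ("N", (5, 0, 0)), ("O", (9, 0, 0)),
                    ("C", (12, 0, 0))], bonds=[])
        matches = match_substructure(g, "[#7,#8]")
        assert sorted(matches) == [(0,), (1,), (2,)]

    def test_aromatic_cc_needs_aromatic_bond_orders(self):
        frag = FRAGMENTS["benzene"]
        spec = list(zip(frag.elements, frag.coords))
        aromatic = _graph(spec, bonds=list(frag.bonds))
        assert match_substructure(aromatic, "cc")
        single = _graph(spec, bonds=[(i, j, 1) for i, j, _o in frag.bonds],
                        provenance="geometric")
        assert match_substructure(single, "cc") == []

    def test_tetrahydropyran_ring_pattern(self):
        frag = FRAGMENTS["thp"]
        g = _graph(list(zip(frag.elements, frag.coords)), bonds=list(frag.bonds))
        assert match_substructure(g, "C1OCCCC1")

    def test_invalid_smarts_raises(self):
        g = _graph([("C", (0, 0, 0))], bonds=[])
        with pytest.raises(ValueError):
            match_substructure(g, "C1C(")


class TestMinDistance:
    def test_coincident_atom_gives_zero(self):
        g = _graph([("O", (1.0, 2.0, 3.0))], bonds=[])
        assert min_distance([(0,)], g, (1.0, 2.0, 3.0)) == 0.0

    def test_minimum_of_a_pair(self):
        g = _graph([("O", (4.9, 0, 0)), ("N", (6.2, 0, 0))], bonds=[])
        assert min_distance([(0,), (1,)], g, (0, 0, 0)) == pytest.approx(4.9)

    def test_matches_exhaustive_scan_on_random_atoms(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(-10, 10, size=(50, 3))
        q = rng.uniform(-10, 10, size=3)
        g = _graph([("O", tuple(c)) for c in coords], bonds=[])
        got = min_distance([(i,) for i in range(50)], g, q)
        # independent oracle: plain all-atoms scan
        expected = min(float(np.sqrt(((c - q) ** 2).sum())) for c in coords)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_atom_sets_rejected(self):
        g = _graph([("O", (0, 0, 0))], bonds=[])
        with pytest.raises(ValueError):
            min_distance([], g, (0, 0, 0))


# The six reachable rows of the filter truth table, realized geometrically:
# an oxygen graph either contains the pattern or not, placed inside or
# outside a 5.5 Å sphere around the origin.
NEAR_O = [("O", (4.9, 0.0, 0.0)), ("C", (6.3, 0.0, 0.0))]
FAR_O = [("O", (8.0, 0.0, 0.0)), ("C", (9.4, 0.0, 0.0))]
NO_O = [("C", (4.9, 0.0, 0.0)), ("C", (6.3, 0.0, 0.0))]


class TestTruthTable:
    @pytest.mark.parametrize(
        "spec, exclude, has_sub, within, expected",
        [
            (NO_O, False, False, None, False),   # no sub, include -> Fail
            (NO_O, True, False, None, True),     # no sub, exclude -> Pass
            (FAR_O, False, True, False, False),  # sub, include, outside -> Fail
            (NEAR_O, False, True, True, True),   # sub, include, within -> Pass
            (FAR_O, True, True, False, True),    # sub, exclude, outside -> Pass
            (NEAR_O, True, True, True, False),   # sub, exclude, within -> Fail
        ])
    def test_all_six_reachable_combinations(self, spec, exclude, has_sub,
                                            within, expected):
        g = _graph(spec, bonds=[(0, 1, 1)])
        v = evaluate_filter(g, _filter("[#7,#8]", 5.5, exclude=exclude))
        assert v.has_substructure is has_sub
        assert v.within_cutoff is within
        assert v.passed is expected

    def test_within_cutoff_is_inclusive(self):
        g = _graph([("O", (5.5, 0.0, 0.0))], bonds=[])
        v = evaluate_filter(g, _filter("[#8]", 5.5))
        assert v.within_cutoff and v.passed

    @pytest.mark.parametrize("spec", [NEAR_O, FAR_O])
    def test_exclude_duality_when_substructure_present(self, spec):
        g = _graph(spec, bonds=[(0, 1, 1)])
        inc = evaluate_filter(g, _filter("[#7,#8]", 5.5, exclude=False))
        exc = evaluate_filter(g, _filter("[#7,#8]", 5.5, exclude=True))
        assert inc.passed is (not exc.passed)

    def test_cutoff_monotonicity(self):
        g = _graph(NEAR_O, bonds=[(0, 1, 1)])
        for c in (5.0, 6.0, 8.0, 20.0):
            assert evaluate_filter(g, _filter("[#8]", c)).passed
        # reversed for exclude filters
        for c in (4.0, 4.8):
            assert evaluate_filter(g, _filter("[#8]", c, exclude=True)).passed
        for c in (5.0, 20.0):
            assert not evaluate_filter(g, _filter("[#8]", c, exclude=True)).passed


class TestEvaluatePose:
    def test_conjunction_all_pass(self):
        g = _graph(NEAR_O, bonds=[(0, 1, 1)])
        ok, verdicts = evaluate_pose(g, [_filter("[#8]", 5.5),
                                         _filter("[#6]", 7.0)])
        assert ok and len(verdicts) == 2

    def test_one_failing_filter_fails_the_pose(self):
        g = _graph(NEAR_O, bonds=[(0, 1, 1)])
        ok, _ = evaluate_pose(g, [_filter("[#8]", 5.5),
                                  _filter("[#6]", 7.0),
                                  _filter("[#7]", 5.5)])  # no N present
        assert not ok

    def test_empty_filter_list_is_vacuously_true(self):
        g = _graph(NO_O, bonds=[(0, 1, 1)])
        ok, verdicts = evaluate_pose(g, [])
        assert ok and verdicts == []


# --------------------------------------------------------------------------
# Independent brute-force evaluator used as an oracle for the engine.

def brute_force_pose_verdict(pose: PoseRecord, filters, mode_graph=None) -> bool:
    """Naive re-implementation: per-element substructure enumeration for
    1-atom patterns, bond-scan for 2-atom patterns, all-atom distance scan.
    Understands the patterns the fixture filters use."""
    graph = mode_graph if mode_graph is not None else infer_bonds_geometric(pose)
    elements = [a.element for a in graph.atoms]
    coords = graph.coords_array()

    def pattern_atoms(smarts):
        if smarts in ("[#7,#8]", "[N,O]"):
            return [{i} for i, el in enumerate(elements) if el in ("N", "O")]
        if smarts in ("[#8]", "[O]"):
            return [{i} for i, el in enumerate(elements) if el == "O"]
        if smarts == "cc":
            return [{i, j} for i, j, o in graph.bonds
                    if o == 4 and elements[i] == "C" and elements[j] == "C"]
        raise NotImplementedError(smarts)

    for f in filters:
        sets = pattern_atoms(f.smarts)
        if not sets:
            if not f.exclude:
                return False
            continue
        q = np.asarray(f.query_point)
        d = min(float(np.linalg.norm(coords[i] - q))
                for s in sets for i in s)
        if (d <= f.cutoff) == f.exclude:
            return False
    return True


class TestOracleEquivalence:
    def test_engine_equals_brute_force_on_seeded_fixture_poses(self, screen7):
        """On 200+ generated poses (each well under 30 atoms), the engine's
        per-pose verdict equals the naive all-pairs evaluator."""
        from posegrep.engine import _evaluate_file, _graphs_for_file
        from posegrep.filters import load_filters
        from posegrep.structures import discover_compound_files, read_poses, read_receptor

        receptor = read_receptor(screen7["receptor"])
        filters = [resolve_query_point(d, receptor)
                   for d in load_filters(screen7["filters"])]
        n_checked = 0
        for path in discover_compound_files(screen7["compounds"]):
            poses = read_poses(path)
            pairs = _graphs_for_file(path, poses, "NONE", None, None, [])
            for pose, graph in pairs:
                engine_ok, _ = evaluate_pose(graph, filters)
                assert engine_ok == brute_force_pose_verdict(pose, filters, graph), \
                    f"{path.name} pose {pose.pose_index}"
                assert len(pose.atoms) <= 30
                n_checked += 1
        assert n_checked >= 200


class TestRunScreen:
    def test_ground_truth_recovery_on_small_fixture(self, small_screen):
        receptor, compounds, filters, truth = small_screen
        res = run_screen(receptor, compounds, filters, mode="NONE")
        assert res.passing_files() == truth.passing_files()
        for name, (ok, poses) in truth.expected.items():
            if ok:
                assert tuple(res.passes[name]) == poses

    def test_corrupt_file_is_skipped_not_fatal(self, tmp_path):
        from posegrep.fixtures import FixtureSpec, make_screen_fixture
        spec = FixtureSpec(seed=13, n_compounds=5, poses_per_compound=1,
                           corrupt_fraction=0.2)
        receptor, compounds, filters, truth = make_screen_fixture(tmp_path, spec)
        res = run_screen(receptor, compounds, filters, mode="NONE")
        assert len(res.skipped) == len(truth.corrupt_files) == 1
        assert res.n_seen == 6
        assert res.passing_files() == truth.passing_files()

    def test_output_file_is_lexicographic(self, small_screen, tmp_path):
        receptor, compounds, filters, _truth = small_screen
        res = run_screen(receptor, compounds, filters, mode="NONE")
        out = tmp_path / "passing.txt"
        res.write_output(out)
        lines = out.read_text().splitlines()
        assert lines == sorted(lines)

    def test_worker_count_does_not_change_output(self, small_screen, tmp_path):
        receptor, compounds, filters, _truth = small_screen
        outs = []
        for jobs in (1, 4):
            res = run_screen(receptor, compounds, filters, mode="NONE", jobs=jobs)
            p = tmp_path / f"out_{jobs}.txt"
            res.write_output(p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_missing_smi_companion_falls_back_with_warning(self, tmp_path):
        from posegrep.fixtures import FixtureSpec, make_screen_fixture
        spec = FixtureSpec(seed=17, n_compounds=4, poses_per_compound=1,
                           formats=("PDBQT",))
        receptor, compounds, filters, truth = make_screen_fixture(tmp_path, spec)
        for smi in compounds.glob("*.smi"):
            smi.unlink()
        res = run_screen(receptor, compounds, filters, mode="SMILES")
        assert any("no .smi companion" in w for w in res.warnings)
        assert res.passing_files() == truth.passing_files()

    def test_filtering_only_removes_never_reorders(self, small_screen):
        """Survivors of a screen appear in the same relative order as the
        full lexicographic file list."""
        receptor, compounds, filters, _truth = small_screen
        from posegrep.structures import discover_compound_files
        everything = [p.name for p in discover_compound_files(compounds)]
        res = run_screen(receptor, compounds, filters, mode="NONE")
        survivors = res.passing_files()
        positions = [everything.index(s) for s in survivors]
        assert positions == sorted(positions)
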