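# posegrep

Post-docking pose filtering for structure-based virtual screening, plus the
enrichment metrics to measure what the filtering buys you.

## The problem

A virtual screen docks thousands of small molecules into a protein target
and ranks them by docking score. The score alone ignores *how* a compound
binds: true ligands of a target typically form a handful of critical
interactions (a hydrogen bond to a particular backbone atom, a π-stack
against a particular side chain). Commercial docking suites can filter poses
on such criteria, but popular open-source engines such as AutoDock Vina
cannot. `posegrep` closes that gap: it takes the receptor, a directory of
docked poses, and a JSON list of geometric/substructure filters, and reports
which compounds have at least one pose satisfying every filter.

A filter pairs

* a **SMARTS** substructure pattern (e.g. `[#7,#8]` — any ligand N or O),
* a **3D query point**, given literally (`"coordinate": [x, y, z]`) or as a
  receptor atom (`"receptorAtom": {"chain": "A", "resid": 863, "atomname":
  "CA"}`),
* a **distance cutoff** in Å (`"distance": 5.5`), and
* an optional **`exclude`** flag that inverts the test (the pose must *not*
  place the substructure near the point).

A pose passes a filter when the minimum distance from any substructure atom
to the query point is ≤ the cutoff (inverted under `exclude`; a pose lacking
the substructure fails a normal filter and passes an exclude filter).
Filters combine by Boolean AND; a compound passes when **any** of its poses
passes all filters — so a plausible second-ranked pose can rescue a compound
whose top pose is implausible.

Because PDB/PDBQT poses carry no bond orders, three bond-assignment modes
are provided: **NONE** (single bonds between atoms within covalent-radius
distance; fine for single-bond SMARTS and for SDF input, which keeps its own
bond block), **SMILES** (map bond orders from a per-compound `.smi`
companion file by graph isomorphism; needed for aromatic patterns such as
`cc`), and **OPENBABEL** (delegate perception to an external Open Babel
executable).

## Scoring a screen

For a ranked library of `T` compounds containing `P_T` known ligands
(positive controls), the enrichment factor at depth `n` is

```
EF_n = P_n / (n · P_T / T)
```

with `P_n` the positives among the top `n` — observed hits over hits
expected under random ordering. To score a filtered screen, compounds whose
poses failed the filters are moved to the bottom of the ranking (a stable
partition) before computing `EF_n`, top-`n` hit counts, and percentile
ranks.

## Worked example

Generate a synthetic screen with known ground truth, then filter it:

```bash
posegrep-fixtures --seed 7 --out demo --n-compounds 20
posegrep demo/receptor.pdb demo/compounds demo/filters.json \
    --mode NONE --out demo/passing.txt --sidecar demo/details.tsv
```

which prints

```
designed passes: 8 / 20
8 of 20 compound files passed (0 skipped); list written to demo/passing.txt
```

`demo/passing.txt` lists the eight passing compound files (lexicographic
order), exactly the eight the generator designed to pass; the sidecar shows
per-pose distances, e.g. `cmpd_0000.pdbqt` fails the `[#7,#8] @ A:863:CA
<= 5.5 Å` filter in pose 1 (min distance 31.2 Å) but passes in pose 2
(3.2 Å) — a compound rescued by a non-top pose.

Scoring a labelled ranking (`compound_id  score  label  passed` TSV):

```bash
posegrep-metrics ranking.tsv --depths 10,20,40 --filtered
```

prints hit counts and `EF_n` at each depth after moving filter failures to
the bottom. As a library, `posegrep.enrichment_factor` on a screen of
T = 1561 compounds with P_T = 46 knowns and 5 of them in the top 10 gives
EF₁₀ = 5/(10·46/1561) ≈ 16.97.

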