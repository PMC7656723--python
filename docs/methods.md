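# Methods

## The filtering model

A docked-compound library is screened pose by pose. Each filter is a
four-tuple (SMARTS pattern, 3D query point, cutoff distance, exclude flag).
For one pose the evaluation is:

1. find every embedding of the SMARTS pattern in the pose's molecular graph;
2. if embeddings exist, compute the minimum Euclidean distance from the
   query point to any atom in any embedding;
3. decide per the truth table below; filters combine by conjunction, and a
   compound passes when at least one pose passes all filters.

| has substructure | exclude | within cutoff | result |
|---|---|---|---|
| no  | no  | n/a | fail |
| no  | yes | n/a | pass |
| yes | no  | no  | fail |
| yes | no  | yes | pass |
| yes | yes | no  | pass |
| yes | yes | yes | fail |

"Within cutoff" is inclusive (`d ≤ cutoff`): ties at the boundary count as
contact, the conventional reading of a distance constraint. Receptor and
pose coordinates are taken as-is — the docking run is assumed to have left
both in one frame, and no transformation is ever applied.

Assumptions: filters are purely geometric (no hydrogen-bond angle terms, no
feature typing beyond SMARTS); hydrogens participate in distances only if
they survive the input format (PDBQT strips nonpolar H) *and* match the
pattern, so heavy-atom patterns like `[#7,#8]` are hydrogen-independent by
construction.

## Bond assignment

PDB/PDBQT poses carry no bonds, so a graph must be built before SMARTS
matching:

* **NONE (geometric).** Atoms *i, j* are singly bonded iff
  `0.4 Å ≤ d(i,j) ≤ r_i + r_j + 0.45 Å`, with Cordero single-bond covalent
  radii. The 0.45 Å additive tolerance accepts the bond-length distortion
  typical of docked geometries without fusing nonbonded contacts
  (shortest C···C nonbonded contacts sit near 2.4 Å, well above the
  1.97 Å C–C threshold); the 0.4 Å floor rejects coincident-atom artifacts.
  Both the radius table and the tolerance are configurable
  (`CovalentRadiusTable`). All atoms are treated as sp³, so aromatic or
  higher-order SMARTS can never match — a load-time advisory warns when
  such a pattern is combined with this mode.
* **SMILES.** The user supplies one SMILES per compound file
  (`name.pdbqt.smi`). The template's heavy-atom graph is matched to the
  heavy-atom subgraph of the geometric connectivity by an element-labelled
  graph isomorphism (networkx `GraphMatcher`); bond orders are copied over
  the mapping. Stereochemistry, formal charge and hydrogen counts do not
  constrain the match — docked PDBQT files carry none of them reliably.
  When several mappings exist (symmetric molecules) the first is used:
  automorphic mappings carry identical bond orders, so the filter outcome
  is mapping-invariant (asserted in tests). A missing companion, an
  unparseable SMILES, or an element-multiset mismatch falls back to
  NONE-mode bonds for that file, with a warning. The mapping is computed
  once per file and reused across MODEL blocks (poses are conformers of one
  molecule); it is recomputed only if the atom count changes between blocks.
* **OPENBABEL.** A subprocess contract around any PDB→SDF converter: run
  with `-h` (add all hydrogens); if the converted heavy atoms do not match
  the input, rerun with `-p 7.4` (pH-based protonation); if both fail the
  file is skipped with a warning. The tool is never linked in-process, so
  the core has no dependency on it; tests exercise the contract with stub
  executables.

SDF input bypasses all three modes: its bond block is authoritative and is
transcribed verbatim (V2000 order 4 = aromatic).

RDKit performs all SMARTS/SMILES work. Pose graphs are handed to RDKit
without valence sanitization or kekulization — docked poses with stripped
hydrogens are not valence-complete molecules and must not be "corrected";
aromatic flags are set directly from the stored bond orders.

## Error-handling contract

Problems confined to one compound file (unparseable text, failed bond
assignment, converter failure) become skip records and the run continues,
exiting successfully. Problems with the receptor or the filters file —
including a `receptorAtom` selector that resolves to zero or several atoms —
abort before any pose is read: a filter that cannot be anchored must not
silently pass everything. Malformed coordinate lines within an otherwise
readable file are dropped individually with a warning. Insertion codes and
alternate-location indicators do not participate in receptor-atom matching;
HETATM receptor records are accepted as anchors (cofactor atoms are
legitimate interaction partners).

## Determinism and parallelism

Work units are whole compound files; results are merged in lexicographic
file-name order, so the output is byte-identical for any `--jobs` value and
any directory enumeration order. Parallelism is a performance feature only
(process pool; serial on platforms without fork support).

## Ranking metrics

`EF_n = P_n / (n · P_T / T)`; ties in score are broken lexicographically by
compound id so rankings are reproducible. The percentile convention is
100·r/T for 1-based rank r ("fraction of the library at or above this
rank"), matching the usual "ranked in the top x%" phrasing; no alternative
convention is offered. Filtering is folded into a ranking as a stable
partition (failures to the bottom, both positives and decoys), which
preserves T and P_T and is idempotent. ROC/pROC areas, BEDROC and
significance testing are out of scope.

## The synthetic-data generator

Fixtures emulate the *geometry* of a Vina-style screen: multiple poses per
compound (capped at 18 — up to two tautomer/ionization variants × nine poses
each in the emulated protocol), PDBQT/PDB/SDF output, `.smi` companions, a
small receptor with named anchor atoms (a Gly-863 backbone, a Tyr-907 ring
carbon) at known coordinates. Molecules are assembled from five rigid
fragment templates (ethanol, methylamine, benzene, tetrahydropyran, butane)
with near-ideal bond lengths, so geometric bond inference is unambiguous.
The default screen — 100 compounds, 3 poses each, 40% designed to pass, a
`[#7,#8]` filter at 5.5 Å from the Gly-863 Cα — mirrors the scale and the
filter style of a published screening campaign while staying desk-sized;
ranked-library fixtures default to the scale T≈1561, P_T≈46 of such a
screen.

Designed-to-pass compounds place the matching fragment at a distance drawn
from [max(1.2, 0.25·cutoff), cutoff − 0.6] Å from the query point; failures
place it ≥ 22 Å away (or inside the sphere, for exclude filters). Gaussian
jitter (σ = 0.05 Å, clipped at 0.1 Å) perturbs atoms without crossing any
decision boundary: a 0.2 Å safety margin around every cutoff is enforced,
and each constructed pose is re-verified by a direct distance/substructure
check before being written — a construction that cannot realize its
designed verdict raises instead of silently emitting a wrong truth table.
Passing compounds get a random non-empty subset of passing poses, so some
files pass only through a non-top pose, exercising the pose-OR rule.

What the fixtures do **not** emulate: chemical realism (valence, strain,
conformational energetics), docking scores, receptor flexibility, or the
ambiguity of real bond perception on distorted geometries. Passing tests
therefore demonstrate the correctness of the filtering logic and I/O, not
screening power on real libraries.

## Problem sizes

The test suite and the acceptance script run screens of 10–100 compounds
with 2–3 poses each and ranked libraries of up to 1561 entries; the
Monte-Carlo check of the mean enrichment factor uses 400 shuffled libraries
of 150 compounds. These sizes give exact, reproducible expectations (the
ground-truth comparison is equality, not approximation) while keeping a
full run in seconds.
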