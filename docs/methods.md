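# Methods

## The identification model

`modfinder` treats a protein modification as a small, declaratively
specified chemical pattern and a structure as evidence for it. A
modification definition lists

* one or more **components** — 3-character wwPDB component codes, each slot
  marked `amino-acid` (must be found on a polymer chain) or `non-polymer`
  (must be found among HETATM-style groups), optionally restricted to a
  chain terminus;
* zero or more **linkages** — pairs of component slots with ordered
  candidate atom-name lists that must be joined by a covalent bond.

The three categories differ only in pattern shape, and each gets the
cheapest sound algorithm:

* **Modified residues** (1 amino-acid component, 0 linkages). Deposited
  structures include nonstandard residues in the polymer sequence under
  their own codes, so identification is a pure sequence scan. Geometry is
  deliberately never consulted: a phosphoserine with a disordered
  phosphate is still phosphoserine.
* **Attachments** (amino-acid + non-polymer components, ≥1 linkage).
  Candidate (residue, group) pairs are those whose codes match; the pair is
  reported iff the listed atom pair passes the bond criterion. A group
  bonded to *k* residues under one definition yields *k* records — one per
  bonded pair — because the definition names one bonded pair, and per-pair
  records are what a sequence-track consumer needs. Records are keyed on
  (definition, residue set) so alternate candidate atoms (e.g. HIS NE2 vs
  ND1 both near a zinc) cannot duplicate a record.
* **Cross-links** (≥2 amino-acid components, connected linkage graph).
  Residues are assigned to slots by backtracking; a partial assignment is
  pruned as soon as any fully assigned linkage lacks a detected bond.
  Completed assignments are canonicalized on the sorted residue identity
  set, which removes automorphic duplicates of symmetric patterns
  (CYS–CYS). Definitions are tiny (2–7 residues), so exact search is cheap
  and auditable; a test verifies it equals exhaustive assignment
  enumeration.

Categories are scanned independently and overlaps are not suppressed: a
selenomethionine inside a disulfide-bonded chain legitimately contributes
records in two categories.

Geometry is the sole evidence for attachments and cross-links. SSBOND,
LINK and CONECT records are parsed by the underlying reader but never
used: deposited connectivity metadata is incomplete and inconsistent
across entries, while the distance criterion applies uniformly. Residues
missing a linkage atom (disorder) simply fail to match; nothing is
imputed.

## The bond criterion

Atoms *i, j* are bonded iff
`min_distance <= d_ij <= r(e_i) + r(e_j) + tolerance`.

| parameter | default | meaning |
|---|---|---|
| `tolerance` | 0.4 Å | slack added to the radii sum; absorbs coordinate error and bond-length variation |
| `min_distance` | 0.5 Å | lower cutoff rejecting duplicated/overlapping atoms |
| radii table | bundled | single-bond covalent radii per element (Cordero 2008 consensus values; low-spin Mn/Fe/Co) |
| `default_radius` | 1.5 Å | fallback for elements absent from the table (warns, never aborts) |

The radii are data, not code: a two-column `ELEMENT radius` file overrides
them per scan (`--radii`). Pinning one published compilation makes results
reproducible; nothing in the method depends on which compilation beyond
the thresholds it implies. Hydrogens are never candidates: every
dictionary linkage is heavy-atom, and including riding hydrogens would
only create spurious near-contacts.

`find_close_pairs` builds a KD-tree (scipy) over one selection and queries
with the largest possible threshold `2·r_max + tolerance`, then applies
the exact per-element threshold to each candidate; the result is defined —
and tested, on 100+ random clouds — to equal the brute-force all-pairs
scan. A KD-tree was chosen over a hand-rolled uniform cell grid because it
meets the same contract with far less code to maintain; the contract, not
the data structure, is what the tests pin.

## Structure reading

Parsing is delegated to gemmi and reduced to what identification needs.
Choices that matter:

* **One model.** Multi-model (NMR) files contribute their first model
  unless another is selected; the method annotates entries, not ensembles.
* **Altlocs.** One location per atom name is kept: highest occupancy, ties
  broken by the lexicographically smallest altloc. Bond detection must be
  single-valued per atom.
* **Polymer typing.** mmCIF entity types, or for PDB format gemmi's
  entity setup, which places HETATM residues with known amino-acid parent
  codes (SEP, MSE, …) inside the polymer — exactly the behaviour the
  sequence scan requires. Author chain/residue numbering is the reported
  identity.
* **Waters** (HOH/DOD/WAT) are dropped entirely. **Element symbols** are
  taken from the element column when present, else inferred from the atom
  name; atoms with unresolvable elements are skipped from bond detection
  with a warning.
* The **entry id** is the uppercased file stem (format-independent; PDB
  HEADER idCodes do not survive all round trips).

## Reports

The TSV is one row per (identification, residue) — so a disulfide
contributes two rows, an attachment one row for the amino acid and one for
the group — with the bonded partner atom(s) and distance (2 decimals)
in the last column. Identifications are canonically ordered (category,
definition id, residue keys) and all serialization is byte-deterministic;
rigid motion, record shuffling and PDB↔mmCIF switching of the same entry
produce byte-identical TSVs. Batch scans never abort on a bad entry: the
failure is logged, counted, and reported in the summary, whose
per-definition counts are *entries containing* the definition, not total
occurrences.

## The synthetic fixture generator

The generator emulates exactly the features the method consults:

* polymer chains with standard and nonstandard residue codes, emitted as
  matched PDB and mmCIF renderings of identical coordinates (rounded to
  3 decimals so both formats parse to the same values);
* non-polymer groups placed so that a designated atom pair sits at an
  exact requested distance from a polymer atom (glycans, zinc ions,
  Fe–S clusters — including one group shared by several coordinating
  residues);
* multi-residue cross-linked arrangements, with linkage atoms relocated to
  a site above the chain plane at exact pairwise distances;
* **decoys**: the same placements at `threshold + 0.2 Å`, the sharpest
  false-positive probe, excluded from the truth table.

Everything else is template geometry: extended chains with 3.8 Å Cα
spacing and schematic side chains whose lateral offsets are chosen so no
cross-residue template pair can reach any bond threshold. Plant sites are
anchored above their (spaced) target residues, and a generation-time check
rejects any spec whose planted sites of *different* modifications come
within bonding range, raising a generation error rather than emitting an
ambiguous fixture.

What passing the planted-truth tests shows: the scanning, bond-criterion
and matching logic are exact on inputs whose ground truth is known by
construction, including at-threshold boundaries. What it does not show:
robustness to real-archive phenomena the generator does not emulate —
genuinely ambiguous chemistry, severe disorder, nonstandard atom
nomenclature in legacy entries, occupancy-split ligands, or symmetry
contacts. The structure reader handles the common forms of these
(altlocs, missing elements, missing atoms) conservatively, but archive
recall is not measured here: the published archive-scale counts depend on
a full historical snapshot and complete curated dictionary and are out of
this package's verification surface. A worked archive example
(a two-cluster ferredoxin entry) needs a download, so the suite instead
uses a synthetic two-cluster analogue (`ferredoxin_like_spec`) exercising
the same F3S/SF4 attachment definitions.

## Problem sizes and runtime

The verification suite uses desk-scale inputs chosen to finish in seconds
while still straddling every decision boundary: 1,100 threshold-straddling
atom pairs for the closed-form check; 100 random 200-atom clouds for the
pair-search oracle; 30 random fixtures (≤500 atoms) for the exhaustive
cross-link oracle; 100 seeded fixtures with decoys for planted-truth
recovery; 25 fixtures for tolerance nesting at t ∈ {0.0, 0.2, 0.4, 0.6}.
`scripts/acceptance.py` recomputes all of these from scratch in ~10 s.

## Known limitations

* The starter dictionary is a representative ~25-record subset; archive
  coverage requires the full curated catalogue (the format supports it).
* Glycan trees are reported via their protein-proximal bond only; no
  saccharide-chain traversal.
* Metal sites use the same distance criterion as everything else — no
  coordination-number or angle checks — and one record per bonded residue,
  not one per site.
* Nucleic-acid modifications, assemblies/symmetry expansion and
  PSI-MOD ontology navigation are out of scope.
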