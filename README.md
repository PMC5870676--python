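# modfinder

Identify protein modifications in 3D macromolecular structures.

Most deposited protein structures carry covalent chemistry beyond the 20
canonical amino acids: phosphorylated or hydroxylated residues, N- and
O-linked glycans, metal-coordination and iron–sulfur sites, disulfide and
isopeptide cross-links. `modfinder` finds these directly from coordinates,
for structural biologists and bioinformaticians who need residue-level
modification annotations for PDB/mmCIF entries (single files or batches)
without relying on deposited metadata such as SSBOND/LINK records.

## Method

Modifications are described declaratively in an XML **dictionary**; each
record names the chemical components involved (3-character wwPDB component
codes) and, where relevant, the atom pairs whose covalent bonding
constitutes the modification. Three identification strategies cover three
categories:

* **Modified residues** (e.g. SEP = phosphoserine) are nonstandard
  components on polymer chains with their own codes; they are identified by
  scanning each chain's sequence and comparing component codes against the
  dictionary. No geometry is consulted.
* **Attachment modifications** (e.g. N-acetylglucosamine on asparagine,
  zinc coordinated by histidine, a 4Fe-4S cluster on cysteines) are found
  geometrically: a polymer residue and a non-polymer group match a
  definition when their codes match and the listed atom pair is covalently
  bonded.
* **Cross-links** (e.g. disulfides, isopeptide bonds) are found by matching
  all involved residues and bonded atom pairs via backtracking over the
  detected-bond graph; symmetric definitions (CYS–CYS) are canonicalized so
  each residue set is reported once.

Two atoms *i, j* at distance *d<sub>ij</sub>* are considered covalently
bonded when

&nbsp;&nbsp;&nbsp;&nbsp;*d*<sub>min</sub> ≤ *d<sub>ij</sub>* ≤ *r*(*e<sub>i</sub>*) + *r*(*e<sub>j</sub>*) + *t*

where *r*(*e*) is the element's single-bond covalent radius (bundled,
pinned table; overridable), *t* is a tolerance (default **0.4 Å**) and
*d*<sub>min</sub> = 0.5 Å rejects coordinate pathologies. The pair search
is KD-tree accelerated and exactly equivalent to a brute-force scan.

A bundled starter dictionary covers ~25 common modifications across all
three categories; the format supports arbitrarily many records
(`modfinder validate-dict` checks one).

## Worked example

Generate a small synthetic entry with one planted modification per category
(plus two near-miss decoys just past the bond threshold), then scan it:

```python
from modfinder import (ScanConfig, identify_all, parse_structure,
                       sequence_track, starter_dictionary)
from modfinder.fixtures import composite_spec, make_fixture

fx = make_fixture(composite_spec(decoys=2), "scratch/demo")
model = parse_structure(fx.pdb_path)
report = identify_all(model, ScanConfig(dictionary=starter_dictionary()))
for m in report.identifications:
    print(m.category.value, m.definition.internal_id,
          [f"{r.component_code} {r.chain_id}{r.seq_id}" for r in m.residues],
          [f"{b.atom_1.atom_name}-{b.atom_2.atom_name} "
           f"{b.distance:.2f} A (thr {b.threshold:.2f})" for b in m.bonds])
```

prints

```
modified-residue phosphoserine ['SEP A3'] []
attachment n-glycosyl-asparagine ['ASN A5', 'NAG X901'] ['ND2-C1 1.43 A (thr 1.87)']
cross-link disulfide ['CYS A7', 'CYS A10'] ['SG-SG 2.05 A (thr 2.50)']
```

— the phosphoserine was found by its component code alone; the
glycosylation site by the ND2–C1 bond (1.43 Å, under the N+C+0.4 = 1.87 Å
threshold); the disulfide by its SG–SG bond (2.05 Å vs the 2×1.05+0.4 =
2.50 Å sulfur threshold). The decoys, placed 0.2 Å past their thresholds,
are correctly absent. Projecting the report onto chain A,

```python
track = sequence_track(report, model, "A")
print([(mk.polymer_index, mk.identification.definition.internal_id,
        mk.n_residues_in_modification) for mk in track.marks])
# [(2, 'phosphoserine', 1), (4, 'n-glycosyl-asparagine', 1),
#  (6, 'disulfide', 2), (9, 'disulfide', 2)]
```

gives one mark per annotated position; the residue count per mark mirrors
the multi-edge icon convention of sequence viewers (a disulfide involves 2
residues, an attachment is reported per bonded residue).

The same scan is available from the shell:

```sh
modfinder scan scratch/demo/cmp1.pdb --out scratch/out --tolerance 0.4
modfinder summary scratch/out
```

writing a per-entry TSV/JSON report (one row per identified residue, with
bonded partner and distance) and a per-definition entry-count summary.

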