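# diatomlox

Sequence taxonomy and regiospecificity prediction for diatom lipoxygenases
(LOX).

Diatoms produce oxylipins — oxygenated fatty-acid derivatives with roles
from plankton ecology to pharmacology — through lipoxygenases that oxidize
polyunsaturated fatty acids at specific carbons. Which carbon is oxidized
(the *LOX-type*: a LOX12 oxidizes C12, numbering from the carboxyl carbon
C1) is determined by the geometry of the enzyme–substrate complex around
the catalytic non-heme iron. `diatomlox` implements, as a tested and
reusable pipeline, the desk-scale part of characterizing these enzymes:

1. **Curation** — candidate protein sequences are kept only if they are
   long enough to span a LOX domain and preserve at least three of the five
   iron-coordination residues (canonically three His, one Asn, one Ile/Leu).
2. **Coordination scanning and classification** — the five coordination
   sites are located by anchored alignment (canonical layout
   `H-x4-H … H-x3-N … I/L`), and the pattern of deviations (a deletion in
   the first His couple, an insertion before the fourth site, substitution
   of the coordinating Asn by His/Gln/Ser, a tandem His) assigns each
   sequence to one of the taxonomy groups 1–6 with subgroups 4a/4b and
   5a/5b.
3. **Phylogenetic grouping** — neighbor joining on Poisson-corrected
   p-distances (d = −ln(1 − p)) with a column bootstrap; groups are maximal
   clades that both exceed the support threshold (95 of 100 replicates) and
   are homogeneous in coordination character; mixed fourth-site clades are
   split into subgroups at fully supported edges.
4. **Pose geometry and regiochemistry** — from a PDB structure with an Fe
   ion and a docked fatty acid, the package extracts the chain carbon
   nearest the iron (Cn), the carboxyl-head orientation, and the state of
   the oxygen-channel gate residue (Gly = open, Ala = closed). The
   oxidation carbon is then n ± 2: an open channel delivers O₂ at the
   candidate toward the pocket entrance, a closed channel drives it to the
   deep-side candidate.

Every stage is also exercised against seeded synthetic fixtures (implanted
coordination motifs; idealized pocket structures) generated by the package
itself, with machine-readable truth files.

## Worked example

The control setup for the rule is arachidonic acid in a coral LOX pose:
20-carbon chain, C10 nearest the iron, carboxyl head outside the pocket,
glycine gate. Changing only the gate to alanine (as in the *P. arenysensis*
enzyme) moves the attack from C8 to C12:

```sh
$ diatomlox call-lox-type --nearest 10 --length 20 \
    --orientation head-external --gate-state closed
{
 "lox_type": "LOX12",
 "nearest": 10,
 "oxidation": 12,
 "candidates": [8, 12],
 "orientation": "HEAD_EXTERNAL",
 "gate": "CLOSED",
 "flags": [],
 "rationale": {"external_side": 8, "deep_side": 12, "gate_open": false}
}
```

The full sequence pipeline on a generated fixture bundle:

```sh
$ diatomlox simulate sequences --seed 1 --per-group 3 --out-dir demo
$ diatomlox run-all --fasta demo/sequences.fasta --anchors demo/anchors.json \
    --out-dir demo/out --bootstrap 100 --seed 7 \
    --group1-motif WDERFKAY --group2-motif YMCKWQPE
INFO diatomlox: run-all: curation kept 24 of 24
INFO diatomlox: run-all: seed=7 B=100 -> 6 groups, 8 terminal labels
```

`demo/out/` then holds the curation report (TSV), the per-sequence
coordination patterns and labels (TSV), the bootstrap tree (Newick, support
values on internal nodes) and the group partition (TSV): six top-level
groups, with groups 4 and 5 each split into two subgroups by the residue at
the fourth coordination site.

Structure-side, `diatomlox simulate pocket` writes an idealized pocket PDB
and `diatomlox pose-report` / `call-lox-type --pdb …` analyze it.

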