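# Methods

## The coordination sphere as a taxonomic character

The LOX catalytic iron is ligated by five residues with a stereotyped
sequence layout: two histidines separated by four residues in the first
half of the domain (H1, H2), a third histidine followed after three
residues by an asparagine in the second half (H3, X4), and a hydrophobic
residue (Ile/Leu) at the C-terminus (T5). Diatom LOXs deviate from this
canon in recurring, group-defining ways, and the package encodes the
taxonomy as a decision table over four observables — the spacing s1
(residues strictly between H1 and H2), the spacing s2 (between H3 and X4),
the identity of X4, and whether H3 is immediately followed by a second
histidine (tandem):

| s2 | condition                | group |
|----|--------------------------|-------|
| 4  | X4 = N                   | 4a    |
| 4  | X4 = Q                   | 4b    |
| 4  | X4 = S                   | 5a    |
| 4  | X4 = H                   | 5b    |
| 3  | s1 < 4 and X4 = H        | 3     |
| 3  | X4 = N, tandem His       | 6     |
| 3  | X4 = N, group-2 motif    | 2     |
| 3  | X4 = N, group-1 motif    | 1     |
| 3  | X4 = N, no motif decides | unresolved 1/2 |
| otherwise                     | unclassified |

Operationalizations that the source material leaves open, decided here
once: the group-3 "deletion" is any s1 < 4; the group-4/5 "insertion" is
exactly s2 = 4 (one extra residue; s2 > 4 is unclassified); T5 accepts
Ile/Leu/Val (Val is observed replacing Ile at an equivalent position);
the ambiguity letter X never matches a site identity. In the tandem-His
case the first histidine of the pair is taken as the coordinating one.
Groups 1 and 2 share the canonical pattern and differ only by a
discriminating motif each; the motifs are configuration inputs (a small
pattern dialect: literals, character classes `[ST]`, wildcards `x`,
bounded gaps `x(2,4)`), and without them the label stays unresolved until
the tree stage settles it by clade co-membership.

## Site scanning

Sites are located by projection, not by motif search: the query is globally
aligned (BLOSUM62, gap open −11, extend −1) to the best-identity member of
an annotated reference set, the reference's five site positions are mapped
through the alignment, and each projected position is verified locally —
the expected residue class (H for H1–H3, [NHQS] for X4, [ILV] for T5) must
occur at the projected position or within ±2 residues of it, downstream of
the previously accepted site. The ±2 window absorbs small alignment jitter;
positions that fail verification are reported as not found. Queries whose
best alignment identity is below 10% are treated as unalignable
(completeness 0). Curation keeps a sequence iff it reaches the minimum
length (default 200 residues — the "fragment" threshold is a package
convention, not an inferred value) and preserves at least `min_sites`
(default 3) of the five sites; completeness 0 is reported separately as
"no domain".

## Tree stage

Downstream only clade membership and support are consumed, so the tree
stage favors determinism over likelihood optimization: pairwise global
alignments give p-distances over aligned non-gap columns, Poisson-corrected
as d = −ln(1 − p) with p clamped at 0.95 (d ≈ 3.0); neighbor joining uses
the Saitou–Nei Q-criterion with ties broken by lowest pair index and
negative branch lengths clamped to zero. Bootstrap columns come from a
progressive multiple alignment over the NJ guide tree; sub-alignments are
merged by aligning their column-plurality consensus sequences and
projecting the resulting gaps into every member row — adequate for column
resampling, not a publication-grade aligner. Supports count, over B = 100
column-resampled replicates, how often each internal bipartition of the
main tree recurs.

Grouping applies a joint criterion: a supported clade (support strictly
above the threshold, default 95) only becomes a group if its members are
homogeneous in group family — by classifier label when labels are supplied
(the unresolved-1/2 label is compatible with both), otherwise by the
pattern signature (deletion flag, s2, tandem, X4 family {N,Q} vs {S,H}).
Support alone is not sufficient: chance attractions between unrelated
families are reproduced faithfully by column resampling (the star-tree
effect) and can exceed any fixed support threshold, whereas they are never
homogeneous in coordination character. Maximal such clades become groups;
leaves covered by none form one residual group; groups containing two
distinct X4 identities are split into subgroups at fully supported
(support = B) internal edges separating the identities, with leftovers
grouped by their own X4 residue.

## Pose geometry and the regiochemistry rule

From a PDB pose the package extracts: the unique Fe position; the ligand
carbon chain, ordered by a connectivity walk (C–C bonds ≤ 1.9 Å) from the
carboxyl carbon (the carbon bonded to two oxygens within 1.6 Å), with
double bonds recorded where a step is ≤ 1.40 Å; the nearest-to-iron carbon
index n (ties within 0.05 Å flagged, lower index reported); the pocket
frame (mouth = gate-residue Cα, bottom = centroid of configured
pocket-bottom residues, depth measured along the mouth→bottom axis); the
head orientation (head-internal iff C1 projects deeper than the terminal
carbon); and the gate state (glycine = open, anything else = closed, with
non-Gly/Ala flagged). Gate and bottom residues are per-structure
configuration — there is no automatic pocket detection — and crystal
waters are ignored.

The rule itself: hydrogen abstraction at Cn puts the oxidation at n − 2 or
n + 2. The two candidates are labeled by pocket side — with the carboxyl
head external, n − 2 lies toward the entrance and n + 2 toward the bottom;
with the head buried the mapping flips. An open gate selects the
entrance-side candidate, a closed gate the deep-side one. The geometric
route implements the same selection metrically (candidate nearest the
mouth when open, nearest the bottom when closed) and the two routes agree
on every generated fixture by construction. When one candidate falls off
the chain the other is used and flagged; a chosen carbon that does not
flank a recorded double bond is flagged rather than rejected.
Stereochemistry (R/S) is out of scope; calls are regiochemical only.

Two documented poses are known not to follow the n ± 2 side-selection
logic (an EPA pose called at position 9 from C6, and a head-in pose called
LOX15 from C13 where the rule gives 11); neither has a stated mechanism
and neither is part of the acceptance surface. They are retained here as
known outliers of the rule.

## Synthetic fixtures

The sequence generator emulates the study conditions rather than real
diatom proteomes: backgrounds are uniform over the 20 amino acids,
600–750 residues long, and the six top-level groups radiate star-like from
one common ancestor (each group background is the ancestor point-mutated at
45% of positions). The star geometry is deliberate — between-group
distances are large but unsaturated, and no structure above the group
level is real, so the grouping stage must neither merge nor invent
superclades. Subgroups (4a/4b, 5a/5b) share their group's background
diverged at 5%, and members within a family carry 2% point mutations
outside the implanted-site windows and motifs. Site neighborhoods (±2) are
sanitized so that no stray residue of a site's class shadows the implant;
this is what makes exact implant recovery a fair test of the scanner
rather than of luck. What passing these tests does *not* show: robustness
to real-world length variation, indels inside the coordination region,
compositional bias, or genuinely ambiguous domain boundaries.

The pocket generator builds an idealized cavity: mouth at the origin,
bottom 15 Å down the axis, Fe midway, the gate residue's Cα at the mouth
and two marker residues at the bottom. The fatty-acid chain runs parallel
to the axis at a 1.6 Å lateral offset with small alternating kinks, bond
steps of 1.52 Å (1.33 Å at double bonds, placed every third bond from C5),
shifted so the requested carbon sits exactly at the iron's depth; the
construction is validated to give that carbon a unique nearest-to-iron
margin of at least 0.4 Å. These are geometric scaffolds, not physical
conformers: no sterics, no protonation, no docking energetics.

## Numerical choices and determinism

All tie-breaks are by lowest index (NJ pair selection, equidistant
candidate carbons); bootstrap replicates draw from one
`numpy.random.default_rng(seed)` stream; generators are bit-reproducible
given (seed, parameters). Distances are in Å; residue numbering follows
the input file. Problem sizes used by the shipped tests — families of 2–4
members (16–32 sequences of ~600–750 residues), bootstrap B = 100 on
8-taxon fixtures, pockets of 16–28 carbons — were chosen as the smallest
sets on which every claimed property is informative.

## Known limitations

The tree stage is a deliberate, declared substitute for a
maximum-likelihood search: NJ on Poisson distances with a consensus-merge
progressive alignment is adequate for clade membership and support on the
fixture regime but is not a phylogenetics replacement for divergent real
sequences. The coordination-domain proxy (pattern completeness) replaces
profile/HMM domain detection. Double-bond inference by distance threshold
is fixture-oriented; real docked poses should supply a bond-order sidecar.
The 5a subgroup is reported to carry Ser at the fourth site in only ~70%
of its members; the identity in the remainder is undocumented, so such
sequences may legitimately land in group 4a or unclassified.
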