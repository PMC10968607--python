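"""Locating and classifying the iron-coordination sphere of LOX sequences.

The lipoxygenase catalytic iron is canonically ligated by five residues laid
out along the sequence in a stereotyped way: two histidines in the first half
of the domain separated by four residues (H-x4-H), a third histidine in the
second half followed by an asparagine after three residues (H-x3-N), and a
terminal isoleucine/leucine.  Diatom LOXs deviate from this canon in a small
number of recurring ways — a deletion between the first histidine couple, an
extra residue inserted before the fourth site, and substitution of the
coordinating asparagine by His, Gln or Ser — and those deviations, together
with two discriminating sequence motifs, define the group taxonomy this
module assigns.

Scanning is anchor-based: the query is globally aligned to the best-matching
annotated reference sequence, the reference's five site positions are
projected through the alignment, and each projected position is verified
locally (the expected residue class must occur within +/-2 positions).
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .curation import ALLOWED_RESIDUES, ProteinRecord

__all__ = [
    "SiteRole",
    "CoordinationSite",
    "CoordinationPattern",
    "GroupLabel",
    "MotifConfig",
    "AnchorSet",
    "scan_coordination",
    "classify_pattern",
    "compile_motif",
]


class SiteRole(str, enum.Enum):
    """The five coordination positions, in sequence order."""

    H1 = "H1"
    H2 = "H2"
    H3 = "H3"
    X4 = "X4"  # canonical Asn; His/Gln/Ser in some groups
    T5 = "T5"  # terminal hydrophobic (Ile/Leu, occasionally Val)


#: Residue classes accepted at each site during local verification.
SITE_CLASSES: dict[SiteRole, frozenset[str]] = {
    SiteRole.H1: frozenset("H"),
    SiteRole.H2: frozenset("H"),
    SiteRole.H3: frozenset("H"),
    SiteRole.X4: frozenset("NHQS"),
    SiteRole.T5: frozenset("ILV"),
}

#: Window (in positions either side of the projected column) searched during
#: verification; absorbs small alignment jitter.
VERIFY_WINDOW = 2

#: Alignment identity below which projection is considered degenerate.
MIN_IDENTITY = 0.10


@dataclass(frozen=True)
class CoordinationSite:
    role: SiteRole
    found: bool
    position: int | None = None  # 0-based index into the sequence
    residue: str | None = None

    def __post_init__(self) -> None:
        if self.found and (self.position is None or self.residue is None):
            raise ValueError(f"{self.role}: found site needs position and residue")


@dataclass(frozen=True)
class CoordinationPattern:
    """The located coordination sphere of one sequence.

    ``s1`` counts residues strictly between H1 and H2 (canonical 4); ``s2``
    counts residues strictly between H3 and X4 (canonical 3).  Either is
    ``None`` when an endpoint was not found.
    """

    record_id: str
    sites: tuple[CoordinationSite, ...]
    s1: int | None
    s2: int | None
    tandem_his_at_H3: bool

    def __post_init__(self) -> None:
        roles = tuple(s.role for s in self.sites)
        if roles != tuple(SiteRole):
            raise ValueError("sites must be the five roles in order")
        positions = [s.position for s in self.sites if s.found]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("found site positions must be strictly increasing")

    @property
    def completeness(self) -> int:
        return sum(1 for s in self.sites if s.found)

    def site(self, role: SiteRole) -> CoordinationSite:
        return self.sites[list(SiteRole).index(role)]

    @property
    def x4_residue(self) -> str | None:
        return self.site(SiteRole.X4).residue


class GroupLabel(str, enum.Enum):
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    G4A = "G4a"
    G4B = "G4b"
    G5A = "G5a"
    G5B = "G5b"
    G6 = "G6"
    UNRESOLVED_12 = "UNRESOLVED_12"
    UNCLASSIFIED = "UNCLASSIFIED"


_MOTIF_TOKEN = re.compile(
    r"(?P<literal>[A-Z])"
    r"|\[(?P<cls>[A-Z]+)\]"
    r"|x\((?P<lo>\d+),(?P<hi>\d+)\)"
    r"|(?P<any>x)"
)


def compile_motif(pattern: str) -> re.Pattern[str]:
    """Compile a motif in the package's small pattern dialect to a regex.

    Dialect: uppercase literals (one-letter amino acids), character classes
    ``[ST]``, single wildcard ``x``, bounded gaps ``x(2,4)``.
    """
    out: list[str] = []
    pos = 0
    while pos < len(pattern):
        m = _MOTIF_TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(f"invalid motif {pattern!r} at offset {pos}")
        if m.group("literal"):
            if m.group("literal") not in ALLOWED_RESIDUES:
                raise ValueError(f"invalid residue {m.group('literal')!r} in motif")
            out.append(m.group("literal"))
        elif m.group("cls"):
            bad = set(m.group("cls")) - ALLOWED_RESIDUES
            if bad:
                raise ValueError(f"invalid residues {sorted(bad)} in motif class")
            out.append(f"[{m.group('cls')}]")
        elif m.group("lo") is not None:
            lo, hi = int(m.group("lo")), int(m.group("hi"))
            if lo > hi:
                raise ValueError(f"empty gap range in motif {pattern!r}")
            out.append(f".{{{lo},{hi}}}")
        else:
            out.append(".")
        pos = m.end()
    return re.compile("".join(out))


@dataclass(frozen=True)
class MotifConfig:
    """Discriminating motifs separating groups 1 and 2.

    Groups 1 and 2 share the canonical coordination pattern and differ only
    by a motif present in one and absent in the other; without configured
    motifs their members are labeled ``UNRESOLVED_12`` (resolvable later by
    tree co-membership).
    """

    group1_motif: str | None = None
    group2_motif: str | None = None

    def __post_init__(self) -> None:
        # validate eagerly so bad config fails before any scanning
        if self.group1_motif is not None:
            compile_motif(self.group1_motif)
        if self.group2_motif is not None:
            compile_motif(self.group2_motif)

    def matches_group1(self, residues: str) -> bool:
        if self.group1_motif is None:
            return False
        return compile_motif(self.group1_motif).search(residues) is not None

    def matches_group2(self, residues: str) -> bool:
        if self.group2_motif is None:
            return False
        return compile_motif(self.group2_motif).search(residues) is not None


@dataclass
class AnchorSet:
    """Reference sequences with annotated coordination-site positions."""

    references: list[ProteinRecord]
    positions: dict[str, dict[SiteRole, int]]  # ref id -> role -> 0-based pos

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("anchor set needs at least one reference")
        for ref in self.references:
            if ref.id not in self.positions:
                raise ValueError(f"no site annotation for reference {ref.id!r}")

    @classmethod
    def load(cls, path: str | Path) -> "AnchorSet":
        """Load a JSON sidecar: list of {id, residues, sites: {role: pos}}."""
        entries = json.loads(Path(path).read_text())
        refs, positions = [], {}
        for e in entries:
            refs.append(ProteinRecord(id=e["id"], residues=e["residues"]))
            positions[e["id"]] = {SiteRole(k): int(v) for k, v in e["sites"].items()}
        return cls(references=refs, positions=positions)

    def save(self, path: str | Path) -> None:
        entries = [
            {
                "id": ref.id,
                "residues": ref.residues,
                "sites": {r.value: p for r, p in self.positions[ref.id].items()},
            }
            for ref in self.references
        ]
        Path(path).write_text(json.dumps(entries, indent=1))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _align_identity(alignment: Align.Alignment) -> float:
    """Fraction of aligned (non-gap) columns with identical residues."""
    a, b = alignment[0], alignment[1]
    aligned = ident = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            aligned += 1
            if x == y:
                ident += 1
    return ident / aligned if aligned else 0.0


def _projection_map(alignment: Align.Alignment) -> dict[int, int]:
    """Map reference positions to query positions through aligned blocks."""
    mapping: dict[int, int] = {}
    ref_blocks, qry_blocks = alignment.aligned
    for (r0, r1), (q0, q1) in zip(ref_blocks, qry_blocks):
        for off in range(r1 - r0):
            mapping[r0 + off] = q0 + off
    return mapping


def _project(pos: int, mapping: dict[int, int], qry_len: int) -> int | None:
    """Project a reference position, extrapolating from the nearest mapped one."""
    if pos in mapping:
        return mapping[pos]
    if not mapping:
        return None
    near = min(mapping, key=lambda r: (abs(r - pos), r))
    proj = mapping[near] + (pos - near)
    return proj if 0 <= proj < qry_len else None


def scan_coordination(
    record: ProteinRecord,
    anchors: AnchorSet,
) -> CoordinationPattern:
    """Locate the five iron-coordination sites of ``record``.

    The query is aligned to each anchor reference; the best-identity
    reference's annotated positions are projected onto the query and locally
    verified: a site is found iff a residue of the expected class (H for
    H1-H3, [NHQS] for X4, [ILV] for T5) occurs at the projected position or
    within ``VERIFY_WINDOW`` residues of it, downstream of the previously
    found site.  A degenerate alignment (identity < 10%) yields completeness
    0.  If H3 lands inside a run of histidines the first of the run is
    reported (the functionally coordinating one in the tandem-His group).
    """
    aligner = _make_aligner()
    best = None
    for ref in anchors.references:
        aln = aligner.align(ref.residues, record.residues)[0]
        ident = _align_identity(aln)
        if best is None or ident > best[0]:
            best = (ident, ref, aln)
    assert best is not None
    identity, ref, alignment = best

    seq = record.residues
    sites: list[CoordinationSite] = []
    if identity < MIN_IDENTITY:
        sites = [CoordinationSite(role=r, found=False) for r in SiteRole]
        return CoordinationPattern(
            record_id=record.id, sites=tuple(sites), s1=None, s2=None,
            tandem_his_at_H3=False,
        )

    mapping = _projection_map(alignment)
    last_found = -1
    for role in SiteRole:
        ref_pos = anchors.positions[ref.id][role]
        proj = _project(ref_pos, mapping, len(seq))
        found_pos: int | None = None
        if proj is not None:
            for delta in (0, -1, 1, -2, 2):
                cand = proj + delta
                if cand <= last_found or not 0 <= cand < len(seq):
                    continue
                if seq[cand] in SITE_CLASSES[role]:
                    found_pos = cand
                    break
        if found_pos is not None and role is SiteRole.H3:
            # report the first His of a contiguous run (tandem-His group)
            while found_pos - 1 > last_found and seq[found_pos - 1] == "H":
                found_pos -= 1
        if found_pos is None:
            sites.append(CoordinationSite(role=role, found=False))
        else:
            sites.append(
                CoordinationSite(
                    role=role, found=True, position=found_pos, residue=seq[found_pos]
                )
            )
            last_found = found_pos

    by_role = {s.role: s for s in sites}
    h1, h2 = by_role[SiteRole.H1], by_role[SiteRole.H2]
    h3, x4 = by_role[SiteRole.H3], by_role[SiteRole.X4]
    s1 = h2.position - h1.position - 1 if h1.found and h2.found else None
    s2 = x4.position - h3.position - 1 if h3.found and x4.found else None
    tandem = bool(
        h3.found and h3.position + 1 < len(seq) and seq[h3.position + 1] == "H"
    )
    return CoordinationPattern(
        record_id=record.id, sites=tuple(sites), s1=s1, s2=s2,
        tandem_his_at_H3=tandem,
    )


def classify_pattern(
    pattern: CoordinationPattern,
    motifs: MotifConfig,
    sequence: ProteinRecord,
) -> GroupLabel:
    """Assign the phylogenetic-pattern group implied by a coordination pattern.

    Decision table, applied in order:

    * insertion before the fourth site (``s2 == 4``): the X4 identity picks
      G4a (Asn), G4b (Gln), G5a (Ser) or G5b (His);
    * canonical spacing (``s2 == 3``): a shortened first couple with His at
      X4 is G3; Asn at X4 with a tandem His at the third site is G6; Asn
      otherwise falls to G2/G1 by discriminating motif, or to
      ``UNRESOLVED_12`` when no motif decides;
    * anything else is ``UNCLASSIFIED``.

    Requires completeness >= 3 (curation should already have filtered).
    """
    if pattern.completeness < 3:
        raise ValueError(
            f"{pattern.record_id}: completeness {pattern.completeness} < 3; "
            "classify only curated patterns"
        )
    s1, s2, x4 = pattern.s1, pattern.s2, pattern.x4_residue
    if s2 == 4:
        return {
            "N": GroupLabel.G4A,
            "Q": GroupLabel.G4B,
            "S": GroupLabel.G5A,
            "H": GroupLabel.G5B,
        }.get(x4 or "", GroupLabel.UNCLASSIFIED)
    if s2 == 3:
        if s1 is not None and s1 < 4 and x4 == "H":
            return GroupLabel.G3
        if x4 == "N":
            if pattern.tandem_his_at_H3:
                return GroupLabel.G6
            if motifs.matches_group2(sequence.residues):
                return GroupLabel.G2
            if motifs.matches_group1(sequence.residues):
                return GroupLabel.G1
            return GroupLabel.UNRESOLVED_12
    return GroupLabel.UNCLASSIFIED


def patterns_table(
    patterns: Sequence[CoordinationPattern],
    labels: Mapping[str, GroupLabel] | None = None,
) -> list[dict[str, object]]:
    """Rows (one per pattern) for the TSV pattern report."""
    rows = []
    for p in patterns:
        row: dict[str, object] = {"id": p.record_id}
        for s in p.sites:
            row[f"{s.role.value}_pos"] = s.position if s.found else ""
            row[f"{s.role.value}_res"] = s.residue if s.found else ""
        row.update(
            s1="" if p.s1 is None else p.s1,
            s2="" if p.s2 is None else p.s2,
            tandem=p.tandem_his_at_H3,
            completeness=p.completeness,
        )
        if labels is not None:
            row["group"] = labels.get(p.record_id, GroupLabel.UNCLASSIFIED).value
        rows.append(row)
    return rows
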