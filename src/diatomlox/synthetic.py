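"""Seeded generators for sequence and structure fixtures with truth files.

Two generators cover everything the pipeline consumes:

* ``make_group_sequences`` emits protein sequences with the coordination
  motif of each taxonomy group implanted at randomized, recorded positions
  on random backgrounds, structured so that family and group relationships
  are recoverable by the tree stage (subgroups of the same group share a
  diverged copy of one background);
* ``make_pocket_fixture`` emits an idealized PDB pocket — Fe on the
  mouth→bottom axis, a gate residue at the mouth, marker residues at the
  bottom, and a fatty-acid carbon chain laid along the axis so that a
  requested carbon is uniquely nearest the iron.

Both are deterministic given (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .coordination import AnchorSet, GroupLabel, MotifConfig, SiteRole
from .curation import ProteinRecord, Source
from .pocket import GateState, GateValue, Orientation
from .regiochem import call_lox_type_categorical

__all__ = [
    "GroupSpec",
    "GROUP_SPECS",
    "DEFAULT_MOTIFS",
    "SequenceTruth",
    "SequenceFixture",
    "make_group_sequences",
    "figure1b_set",
    "PocketTruth",
    "PocketFixture",
    "make_pocket_fixture",
]

_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
#: letters outside every coordination-site residue class, used to sanitize
#: the +/-2 verification window around implanted sites
_SAFE = np.array(list("ACDEFGKMPRTWY"))


@dataclass(frozen=True)
class GroupSpec:
    """Coordination-pattern parameters of one taxonomy group."""

    label: GroupLabel
    s1: int  # residues strictly between H1 and H2
    s2: int  # residues strictly between H3 and X4
    x4: str
    tandem: bool = False
    motif: str | None = None  # "group1" / "group2" discriminator key
    base: str = ""  # background family key; subgroups share a base


#: Default discriminating motifs for groups 1 and 2 (literal dialect).
DEFAULT_MOTIFS = MotifConfig(group1_motif="WDERFKAY", group2_motif="YMCKWQPE")

GROUP_SPECS: tuple[GroupSpec, ...] = (
    GroupSpec(GroupLabel.G1, s1=4, s2=3, x4="N", motif="group1", base="12a"),
    GroupSpec(GroupLabel.G2, s1=4, s2=3, x4="N", motif="group2", base="12b"),
    GroupSpec(GroupLabel.G3, s1=3, s2=3, x4="H", base="3"),
    GroupSpec(GroupLabel.G4A, s1=4, s2=4, x4="N", base="4"),
    GroupSpec(GroupLabel.G4B, s1=4, s2=4, x4="Q", base="4"),
    GroupSpec(GroupLabel.G5A, s1=4, s2=4, x4="S", base="5"),
    GroupSpec(GroupLabel.G5B, s1=4, s2=4, x4="H", base="5"),
    GroupSpec(GroupLabel.G6, s1=4, s2=3, x4="N", tandem=True, base="6"),
)


@dataclass(frozen=True)
class SequenceTruth:
    label: GroupLabel
    sites: dict[SiteRole, int]
    s1: int
    s2: int
    x4: str
    tandem: bool


@dataclass
class SequenceFixture:
    """Generated sequence set: records, per-record truth, anchors, motifs."""

    records: list[ProteinRecord]
    truth: dict[str, SequenceTruth]
    anchors: AnchorSet
    motifs: MotifConfig

    def truth_json(self) -> str:
        return json.dumps(
            {
                rid: {
                    "label": t.label.value,
                    "sites": {r.value: p for r, p in t.sites.items()},
                    "s1": t.s1,
                    "s2": t.s2,
                    "x4": t.x4,
                    "tandem": t.tandem,
                }
                for rid, t in self.truth.items()
            },
            indent=1,
        )


def _implant(
    background: np.ndarray,
    spec: GroupSpec,
    positions: dict[SiteRole, int],
    motifs: MotifConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Write a group's coordination motif (and discriminator) onto a background."""
    seq = background.copy()
    identities = {
        SiteRole.H1: "H",
        SiteRole.H2: "H",
        SiteRole.H3: "H",
        SiteRole.X4: spec.x4,
        SiteRole.T5: "I",
    }
    site_pos = set(positions.values())
    for role, pos in positions.items():
        seq[pos] = identities[role]
        # sanitize the verification window so no stray class member shadows
        # the implanted site (keeps implant recovery exact)
        for off in (-2, -1, 1, 2):
            w = pos + off
            if 0 <= w < len(seq) and w not in site_pos:
                seq[w] = rng.choice(_SAFE)
    if spec.tandem:
        seq[positions[SiteRole.H3] + 1] = "H"
    motif = {"group1": motifs.group1_motif, "group2": motifs.group2_motif}.get(
        spec.motif or ""
    )
    if motif is not None:
        seq[20 : 20 + len(motif)] = list(motif)
    return seq


def _protected_mask(
    length: int, positions: dict[SiteRole, int], spec: GroupSpec
) -> np.ndarray:
    """Positions that per-member mutations must not touch."""
    mask = np.zeros(length, dtype=bool)
    for pos in positions.values():
        lo, hi = max(pos - 2, 0), min(pos + 3, length)
        mask[lo:hi] = True
    if spec.motif is not None:
        mask[20 : 20 + 12] = True
    return mask


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator,
            protected: np.ndarray | None = None) -> np.ndarray:
    """Point-mutate a fraction ``rate`` of positions to a different letter."""
    out = seq.copy()
    free = np.flatnonzero(~protected) if protected is not None else np.arange(len(seq))
    n = min(int(round(rate * len(seq))), len(free))
    if n == 0:
        return out
    pos = rng.choice(free, size=n, replace=False)
    for p in pos:
        choices = _AMINO[_AMINO != out[p]]
        out[p] = rng.choice(choices)
    return out


def make_group_sequences(
    seed: int,
    per_group: int,
    motifs: MotifConfig = DEFAULT_MOTIFS,
    length_range: tuple[int, int] = (600, 750),
    mutation_rate: float = 0.02,
    subgroup_divergence: float = 0.05,
    base_divergence: float = 0.45,
) -> SequenceFixture:
    """Generate ``per_group`` sequences for each of the 8 terminal patterns.

    The six top-level groups radiate star-like from one random ancestor
    (each group background is the ancestor mutated at ``base_divergence``),
    so between-group distances are large but unsaturated and no structure
    above the group level is supported.  Each background carries the group's
    coordination motif: the first histidine couple in the first half, the
    H3/X4 couple in the second half and the terminal hydrophobic site near
    the end.  Subgroups of groups 4 and 5 share their group's background
    (diverged at ``subgroup_divergence``), so the tree stage can recover
    both the six-group and the eight-family structure.  Per-member point
    mutations (``mutation_rate``, outside site windows and motifs) create
    within-family diversity.
    """
    if per_group < 1:
        raise ValueError("per_group must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    ancestor = rng.choice(_AMINO, size=length)

    # one background and one set of site positions per base family
    bases: dict[str, tuple[np.ndarray, dict[SiteRole, int]]] = {}
    for spec in GROUP_SPECS:
        if spec.base in bases:
            continue
        background = _mutate(ancestor, base_divergence, rng)
        h1 = int(rng.integers(40, length // 2 - 20))
        h3 = int(rng.integers(length // 2 + 10, length - 60))
        t5 = int(rng.integers(length - 30, length - 5))
        positions = {
            SiteRole.H1: h1,
            SiteRole.H2: h1 + spec.s1 + 1,
            SiteRole.H3: h3,
            SiteRole.X4: h3 + spec.s2 + 1,
            SiteRole.T5: t5,
        }
        bases[spec.base] = (background, positions)

    records: list[ProteinRecord] = []
    truth: dict[str, SequenceTruth] = {}
    anchor_refs: list[ProteinRecord] = []
    anchor_pos: dict[str, dict[SiteRole, int]] = {}

    for spec in GROUP_SPECS:
        background, base_positions = bases[spec.base]
        # subgroup-level divergence off the shared base
        family_bg = _mutate(background, subgroup_divergence, rng)
        positions = dict(base_positions)
        # spacing differs between subgroups sharing a base only via X4/s2,
        # which GROUP_SPECS pins per terminal label
        positions[SiteRole.H2] = positions[SiteRole.H1] + spec.s1 + 1
        positions[SiteRole.X4] = positions[SiteRole.H3] + spec.s2 + 1
        family_seq = _implant(family_bg, spec, positions, motifs, rng)

        ref_id = f"{spec.label.value}_ref"
        anchor_refs.append(
            ProteinRecord(
                id=ref_id, residues="".join(family_seq), source=Source.FIXTURE
            )
        )
        anchor_pos[ref_id] = dict(positions)

        protected = _protected_mask(length, positions, spec)
        for m in range(1, per_group + 1):
            member = _mutate(family_seq, mutation_rate, rng, protected)
            rid = f"{spec.label.value}_{m}"
            records.append(
                ProteinRecord(
                    id=rid, residues="".join(member),
                    organism=f"synthetic {spec.label.value} family member",
                    source=Source.FIXTURE,
                )
            )
            truth[rid] = SequenceTruth(
                label=spec.label,
                sites=dict(positions),
                s1=spec.s1,
                s2=spec.s2,
                x4=spec.x4,
                tandem=spec.tandem,
            )

    anchors = AnchorSet(references=anchor_refs, positions=anchor_pos)
    return SequenceFixture(records=records, truth=truth, anchors=anchors, motifs=motifs)


#: internal seed of the canned one-sequence-per-pattern reference set
_FIG_SET_SEED = 1403


def figure1b_set(motifs: MotifConfig = DEFAULT_MOTIFS) -> SequenceFixture:
    """The canned idealized reference set: one sequence per terminal pattern."""
    return make_group_sequences(
        seed=_FIG_SET_SEED, per_group=1, motifs=motifs, mutation_rate=0.0,
        subgroup_divergence=0.05,
    )


# ---------------------------------------------------------------------------
# pocket fixtures


@dataclass(frozen=True)
class PocketTruth:
    nearest_carbon: int
    margin: float
    orientation: Orientation
    gate: GateValue
    oxidation_carbon: int
    double_bonds: tuple[int, ...]


@dataclass
class PocketFixture:
    pdb_text: str
    truth: PocketTruth
    ligand_resname: str = "LIG"
    gate: tuple[str, int] = ("A", 427)
    bottom: tuple[tuple[str, int], ...] = (("A", 589), ("A", 620))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.pdb_text)
        return path


_POCKET_DEPTH = 15.0  # Å, mouth to bottom
_LATERAL = 1.6  # Å, chain offset from the pocket axis
_BOND = 1.52
_DOUBLE = 1.33
_MIN_MARGIN = 0.4


def _pdb_structure(
    chain_xyz: np.ndarray,
    oxy_xyz: np.ndarray,
    fe: np.ndarray,
    gate_residue_name: str,
) -> str:
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic pocket"
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")

    def residue(name: str, num: int, het: bool) -> "gemmi.Residue":
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(num, " ")
        res.het_flag = "H" if het else "A"
        return res

    def add_atom(res, name: str, element: str, xyz) -> None:
        a = gemmi.Atom()
        a.name = name
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(*map(float, xyz))
        a.occ = 1.0
        res.add_atom(a)

    gate = residue(gate_residue_name, 427, het=False)
    add_atom(gate, "N", "N", (-1.3, 0.6, 0.4))
    add_atom(gate, "CA", "C", (0.0, 0.0, 0.0))
    add_atom(gate, "C", "C", (1.2, 0.8, 0.3))
    add_atom(gate, "O", "O", (1.3, 1.9, 0.8))
    ch.add_residue(gate)
    for num, dx in ((589, -0.5), (620, 0.5)):
        bottom = residue("ALA", num, het=False)
        add_atom(bottom, "CA", "C", (dx, 0.0, -_POCKET_DEPTH))
        ch.add_residue(bottom)
    fe_res = residue("FE", 701, het=True)
    add_atom(fe_res, "FE", "FE", fe)
    ch.add_residue(fe_res)
    lig = residue("LIG", 801, het=True)
    for k, xyz in enumerate(chain_xyz, start=1):
        add_atom(lig, f"C{k}", "C", xyz)
    for k, xyz in enumerate(oxy_xyz, start=1):
        add_atom(lig, f"O{k}", "O", xyz)
    ch.add_residue(lig)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def make_pocket_fixture(
    n_carbons: int,
    nearest_index: int,
    orientation: Orientation,
    gate_residue_name: str = "GLY",
    seed: int = 0,
) -> PocketFixture:
    """Build an idealized pocket PDB with a controlled nearest carbon.

    The pocket mouth sits at the origin, the bottom at (0, 0, −15) and the
    iron midway on the axis.  The fatty-acid chain runs parallel to the axis
    at a 2 Å lateral offset with small alternating kinks, shifted so the
    requested carbon is at the iron's depth and hence uniquely nearest
    (margin >= 0.4 Å, validated).  C1 carries two carboxyl oxygens; cis
    double bonds (short 1.33 Å steps) are placed every third bond from C5.
    """
    if not 1 <= nearest_index <= n_carbons:
        raise ValueError("nearest_index outside the chain")
    if n_carbons < 3:
        raise ValueError("need at least 3 carbons")
    rng = np.random.default_rng(seed)

    double_bonds = tuple(i for i in range(5, n_carbons, 3) if i < n_carbons)
    bond_lengths = [
        _DOUBLE if (i + 1) in double_bonds else _BOND for i in range(n_carbons - 1)
    ]
    y = 0.15 * (-1) ** np.arange(n_carbons) + rng.uniform(-0.02, 0.02, n_carbons)
    z_steps = [np.sqrt(L**2 - (y[i + 1] - y[i]) ** 2) for i, L in enumerate(bond_lengths)]
    z = np.concatenate([[0.0], -np.cumsum(z_steps)])  # C1 at top, descending
    if orientation is Orientation.HEAD_INTERNAL:
        z = -z  # C1 becomes the deepest carbon
    fe = np.array([0.0, 0.0, -_POCKET_DEPTH / 2])
    z = z - z[nearest_index - 1] + fe[2]  # requested carbon at iron depth
    chain_xyz = np.column_stack([np.full(n_carbons, _LATERAL), y, z])

    dists = np.linalg.norm(chain_xyz - fe, axis=1)
    k = int(np.argmin(dists))
    margin = float(np.partition(dists, 1)[1] - dists[k])
    if k != nearest_index - 1 or margin < _MIN_MARGIN:
        raise ValueError(
            f"cannot place carbon {nearest_index} uniquely nearest the iron "
            f"(got carbon {k + 1}, margin {margin:.2f} Å)"
        )

    # carboxyl oxygens in the +x half-plane, clear of C2
    c1 = chain_xyz[0]
    oxy_xyz = np.array(
        [c1 + (1.0825, 0.625, 0.0), c1 + (1.0825, -0.625, 0.0)]
    )

    gate = GateState(
        value=GateValue.OPEN if gate_residue_name == "GLY" else GateValue.CLOSED,
        residue_name=gate_residue_name,
        residue_number=427,
        nonstandard=gate_residue_name not in {"GLY", "ALA"},
    )
    expected = call_lox_type_categorical(
        n=nearest_index, chain_length=n_carbons, orientation=orientation, gate=gate
    )
    truth = PocketTruth(
        nearest_carbon=nearest_index,
        margin=round(margin, 3),
        orientation=orientation,
        gate=gate.value,
        oxidation_carbon=expected.oxidation,
        double_bonds=double_bonds,
    )
    return PocketFixture(
        pdb_text=_pdb_structure(chain_xyz, oxy_xyz, fe, gate_residue_name),
        truth=truth,
    )
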