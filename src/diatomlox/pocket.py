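"""Geometric analysis of an enzyme–substrate pose around the catalytic iron.

The inputs are docked (or idealized) protein–ligand structures in PDB format
containing a single Fe ion and a polyunsaturated fatty-acid ligand.  The
facts extracted here — which ligand carbon sits nearest the iron, whether
the carboxyl head points out of the pocket or into its depth, and whether
the residue at the top of the oxygen channel is a glycine (open) or an
alanine/other (closed) — are exactly what the regiochemistry rule consumes.

Carbon numbering follows fatty-acid chemistry: C1 is the carboxyl carbon and
numbering proceeds down the chain.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "LigandChain",
    "PocketFrame",
    "GateState",
    "Orientation",
    "load_structure",
    "find_iron",
    "coordination_shell",
    "ligand_chain",
    "nearest_carbon",
    "head_orientation",
    "contacts",
    "hbonds",
    "gate_state",
    "build_frame",
]

#: Maximum C–C distance treated as a covalent bond when walking the chain.
BOND_MAX = 1.9
#: Maximum C–O distance identifying the carboxyl carbon.
CARBOXYL_BOND_MAX = 1.6
#: C–C distances at or below this are flagged as double bonds.
DOUBLE_BOND_MAX = 1.40
#: Two carbons within this margin of the minimum Fe distance count as a tie.
TIE_MARGIN = 0.05


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: tuple[float, float, float]
    icode: str = ""
    hetatm: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz)


class GateValue(str, enum.Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"


@dataclass(frozen=True)
class GateState:
    """State of the upper oxygen-channel gate.

    OPEN iff the gate residue is a glycine; an alanine (or any bulkier
    residue, flagged) occludes the channel mouth and drives O2 deeper.
    """

    value: GateValue
    residue_name: str
    residue_number: int
    nonstandard: bool = False  # neither Gly nor Ala at the gate position

    @property
    def is_open(self) -> bool:
        return self.value is GateValue.OPEN


class Orientation(str, enum.Enum):
    HEAD_EXTERNAL = "HEAD_EXTERNAL"  # carboxyl head toward the pocket mouth
    HEAD_INTERNAL = "HEAD_INTERNAL"  # carboxyl head buried in the pocket


@dataclass(frozen=True)
class LigandChain:
    """An ordered fatty-acid carbon chain with its carboxyl oxygens.

    ``carbons[k]`` is carbon C(k+1); ``double_bonds`` holds 1-based indices i
    meaning a double bond between Ci and Ci+1.
    """

    carbons: tuple[tuple[float, float, float], ...]
    carboxyl_oxygens: tuple[tuple[float, float, float], ...]
    double_bonds: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.carbons:
            raise ValueError("empty carbon chain")
        for i in self.double_bonds:
            if not 1 <= i < self.n:
                raise ValueError(f"double-bond index {i} outside [1, {self.n})")

    @property
    def n(self) -> int:
        return len(self.carbons)

    def carbon(self, index: int) -> np.ndarray:
        """Position of carbon C{index} (1-based chemistry numbering)."""
        if not 1 <= index <= self.n:
            raise IndexError(f"carbon index {index} outside [1, {self.n}]")
        return np.asarray(self.carbons[index - 1])


@dataclass(frozen=True)
class PocketFrame:
    """Reference frame of the catalytic pocket.

    ``mouth`` is the upper oxygen-channel point (gate residue Cα), ``bottom``
    the deep-pocket point (centroid of the configured pocket-bottom
    residues); ``axis`` is the unit vector mouth→bottom, so depth increases
    into the pocket.
    """

    fe: tuple[float, float, float]
    mouth: tuple[float, float, float]
    bottom: tuple[float, float, float]

    def __post_init__(self) -> None:
        if np.linalg.norm(np.subtract(self.bottom, self.mouth)) < 1e-6:
            raise ValueError("degenerate pocket axis: mouth == bottom")

    @property
    def axis(self) -> np.ndarray:
        v = np.subtract(self.bottom, self.mouth)
        return v / np.linalg.norm(v)

    def depth(self, xyz: Sequence[float]) -> float:
        return float(np.dot(np.subtract(xyz, self.mouth), self.axis))


def load_structure(path: str | Path) -> list[Atom]:
    """Parse a PDB file into a flat atom list.

    Elements come from the element column when present, with a fallback to
    the leading letter of the atom name.  Insertion codes are preserved.
    """
    structure = gemmi.read_pdb(str(path))
    atoms: list[Atom] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    element = atom.element.name.upper()
                    if not element or element == "X":
                        element = "".join(
                            c for c in atom.name if c.isalpha()
                        )[:1].upper()
                    atoms.append(
                        Atom(
                            name=atom.name,
                            element=element,
                            res_name=residue.name,
                            res_seq=residue.seqid.num,
                            chain=chain.name,
                            xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                            icode=(residue.seqid.icode or "").strip(),
                            hetatm=residue.het_flag == "H",
                        )
                    )
        break  # first model only
    if not atoms:
        raise ValueError(f"no atoms parsed from {path}")
    return atoms


def find_iron(atoms: Sequence[Atom]) -> np.ndarray:
    """Position of the unique Fe cofactor."""
    irons = [a for a in atoms if a.element == "FE"]
    if not irons:
        raise ValueError("no cofactor: structure contains no Fe atom")
    if len(irons) > 1:
        where = ", ".join(f"{a.res_name} {a.chain}:{a.res_seq}" for a in irons)
        raise ValueError(f"multiple Fe atoms: {where}")
    return irons[0].pos


#: Side-chain (and, for the hydrophobic site, backbone carbonyl) atoms that
#: can ligate the iron.
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def coordination_shell(
    atoms: Sequence[Atom],
    fe_xyz: Sequence[float],
    cutoff: float = 3.0,
) -> list[tuple[str, int, str, float]]:
    """Protein residues with an iron-ligating atom within ``cutoff`` of Fe.

    A residue qualifies if a side-chain N/O/S atom — or its backbone
    carbonyl O, the ligating atom of the C-terminal Ile — lies at distance
    <= cutoff.  Returns (chain, res_seq, res_name, distance), nearest first.
    """
    fe = np.asarray(fe_xyz)
    best: dict[tuple[str, int, str], float] = {}
    for a in atoms:
        if a.hetatm:
            continue
        is_sidechain_donor = a.element in {"N", "O", "S"} and a.name not in _BACKBONE
        is_carbonyl = a.name in {"O", "OXT"}
        if not (is_sidechain_donor or is_carbonyl):
            continue
        dist = float(np.linalg.norm(a.pos - fe))
        if dist <= cutoff:
            key = (a.chain, a.res_seq, a.res_name)
            if dist < best.get(key, np.inf):
                best[key] = dist
    return sorted(
        [(c, n, r, d) for (c, n, r), d in best.items()], key=lambda t: t[3]
    )


def ligand_chain(atoms: Sequence[Atom], ligand_resname: str) -> LigandChain:
    """Extract the ordered fatty-acid carbon chain of the named ligand.

    The carboxyl carbon (C1) is the carbon bonded (<= 1.6 Å) to two oxygens;
    the chain is ordered by a connectivity walk over C–C bonds (<= 1.9 Å).
    Branched carbon graphs are rejected.  Bonds of length <= 1.40 Å are
    recorded as double bonds.  Robust to shuffled atom record order.
    """
    lig = [a for a in atoms if a.res_name == ligand_resname]
    if not lig:
        raise ValueError(f"ligand residue {ligand_resname!r} not found")
    carbons = [a for a in lig if a.element == "C"]
    oxygens = [a for a in lig if a.element == "O"]
    if not carbons:
        raise ValueError(f"ligand {ligand_resname!r} has no carbons")

    cpos = np.array([a.pos for a in carbons])
    # adjacency over C-C bonds
    diff = cpos[:, None, :] - cpos[None, :, :]
    dmat = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dmat, np.inf)
    adj = dmat <= BOND_MAX

    # carboxyl carbon: bonded to two oxygens
    c1_idx = None
    for k, a in enumerate(carbons):
        n_ox = sum(
            1 for o in oxygens if np.linalg.norm(o.pos - a.pos) <= CARBOXYL_BOND_MAX
        )
        if n_ox >= 2:
            if c1_idx is not None:
                raise ValueError("multiple carboxyl carbons in ligand")
            c1_idx = k
    if c1_idx is None:
        raise ValueError("no carboxyl carbon (carbon bonded to two oxygens)")

    degrees = adj.sum(axis=1)
    if np.any(degrees > 2):
        raise ValueError("branched carbon graph: not a simple fatty-acid chain")

    order = [c1_idx]
    seen = {c1_idx}
    while True:
        nbrs = [k for k in np.flatnonzero(adj[order[-1]]) if k not in seen]
        if not nbrs:
            break
        order.append(nbrs[0])
        seen.add(nbrs[0])
    if len(order) != len(carbons):
        raise ValueError(
            f"carbon walk from carboxyl carbon covered {len(order)} of "
            f"{len(carbons)} carbons (disconnected chain)"
        )

    double_bonds = tuple(
        i + 1
        for i in range(len(order) - 1)
        if dmat[order[i], order[i + 1]] <= DOUBLE_BOND_MAX
    )
    carboxyl_o = tuple(
        tuple(o.xyz)
        for o in oxygens
        if np.linalg.norm(o.pos - cpos[c1_idx]) <= CARBOXYL_BOND_MAX
    )
    return LigandChain(
        carbons=tuple(tuple(cpos[k]) for k in order),
        carboxyl_oxygens=carboxyl_o,
        double_bonds=double_bonds,
    )


def nearest_carbon(
    chain: LigandChain, fe_xyz: Sequence[float]
) -> tuple[int, float, bool]:
    """Carbon index (1-based) nearest the iron, its distance, and a tie flag.

    The tie flag is set when a second carbon lies within ``TIE_MARGIN`` Å of
    the minimum; the lower index is reported.
    """
    fe = np.asarray(fe_xyz)
    dists = np.linalg.norm(np.asarray(chain.carbons) - fe, axis=1)
    k = int(np.argmin(dists))
    tie = bool(np.sum(dists <= dists[k] + TIE_MARGIN) > 1)
    return k + 1, float(dists[k]), tie


def head_orientation(chain: LigandChain, frame: PocketFrame) -> Orientation:
    """Whether the carboxyl head (C1) sits deeper in the pocket than the tail."""
    d_head = frame.depth(chain.carbons[0])
    d_tail = frame.depth(chain.carbons[-1])
    return (
        Orientation.HEAD_INTERNAL if d_head > d_tail else Orientation.HEAD_EXTERNAL
    )


def contacts(
    atoms: Sequence[Atom],
    chain_atoms: Sequence[Atom],
    cutoff: float = 4.0,
) -> list[tuple[str, int, str]]:
    """Protein residues with any atom within ``cutoff`` of any ligand atom.

    Unique residues, ordered by (chain, residue number).
    """
    lig_pos = np.array([a.pos for a in chain_atoms])
    found: set[tuple[str, int, str]] = set()
    for a in atoms:
        if a.hetatm:
            continue
        if np.min(np.linalg.norm(lig_pos - a.pos, axis=1)) <= cutoff:
            found.add((a.chain, a.res_seq, a.res_name))
    return sorted(found, key=lambda t: (t[0], t[1]))


def hbonds(
    atoms: Sequence[Atom],
    chain_atoms: Sequence[Atom],
    d_max: float = 3.5,
) -> list[tuple[str, str, int, str, float]]:
    """Ligand O ... protein N/O pairs within ``d_max`` (distance criterion only).

    Returns (ligand atom name, protein chain, res number, protein atom name,
    distance).
    """
    out = []
    lig_ox = [a for a in chain_atoms if a.element == "O"]
    donors = [a for a in atoms if not a.hetatm and a.element in {"N", "O"}]
    for lo in lig_ox:
        for pa in donors:
            d = float(np.linalg.norm(lo.pos - pa.pos))
            if d <= d_max:
                out.append((lo.name, pa.chain, pa.res_seq, pa.name, round(d, 3)))
    return sorted(out, key=lambda t: t[4])


def _residue_atoms(atoms: Sequence[Atom], chain: str, res_seq: int) -> list[Atom]:
    sel = [a for a in atoms if a.chain == chain and a.res_seq == res_seq]
    if not sel:
        raise ValueError(f"residue {chain}:{res_seq} not found")
    return sel


def gate_state(atoms: Sequence[Atom], gate_chain: str, gate_res: int) -> GateState:
    """Open/closed state of the configured oxygen-channel gate residue."""
    res = _residue_atoms(atoms, gate_chain, gate_res)
    name = res[0].res_name
    return GateState(
        value=GateValue.OPEN if name == "GLY" else GateValue.CLOSED,
        residue_name=name,
        residue_number=gate_res,
        nonstandard=name not in {"GLY", "ALA"},
    )


def build_frame(
    atoms: Sequence[Atom],
    fe_xyz: Sequence[float],
    gate: tuple[str, int],
    bottom: Sequence[tuple[str, int]],
) -> PocketFrame:
    """Pocket frame from the gate residue Cα (mouth) and bottom-residue centroid."""
    gate_atoms = _residue_atoms(atoms, *gate)
    ca = [a for a in gate_atoms if a.name == "CA"]
    mouth = (ca[0] if ca else gate_atoms[0]).pos
    bottom_positions = []
    for chain_id, res_seq in bottom:
        for a in _residue_atoms(atoms, chain_id, res_seq):
            bottom_positions.append(a.pos)
    bottom_xyz = np.mean(bottom_positions, axis=0)
    return PocketFrame(
        fe=tuple(np.asarray(fe_xyz)),
        mouth=tuple(mouth),
        bottom=tuple(bottom_xyz),
    )
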