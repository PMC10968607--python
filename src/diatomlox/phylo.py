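"""Distance-based clustering of curated LOX sequences with bootstrap support.

Curated sequences are clustered with neighbor joining on Poisson-corrected
p-distances, with clade confidence from a column bootstrap over a progressive
multiple alignment.  Downstream, only clade membership and support are
consumed: strongly supported clades (support above a threshold, canonically
95 of 100 replicates) become groups, and groups mixing distinct identities at
the fourth iron-coordination site are split into subgroups at fully
supported internal edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .coordination import CoordinationPattern, GroupLabel, SiteRole
from .curation import ProteinRecord

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "SupportTree",
    "distance_matrix",
    "nj_tree",
    "progressive_alignment",
    "bootstrap_supports",
    "extract_groups",
    "GroupPartition",
]

#: p-distances are clamped here before Poisson correction (d = -ln(1-p)
#: diverges as p -> 1); 0.95 maps to d ~ 3.0 substitutions/site.
MAX_P_DISTANCE = 0.95


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) over ordered ids."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")


@dataclass
class TreeNode:
    """Node of a (possibly trifurcating-root) phylogenetic tree."""

    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])  # type: ignore[list-item]
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_names()
        return frozenset(out)


@dataclass
class SupportTree:
    """Unrooted tree stored with a trifurcating root; supports on internal edges."""

    root: TreeNode
    ids: tuple[str, ...]

    def internal_nodes(self) -> list[TreeNode]:
        out = []
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
            stack.extend(node.children)
        return out

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions, keyed by the side not containing ids[0]."""
        n = len(self.ids)
        ref = self.ids[0]
        out: dict[frozenset[str], TreeNode] = {}
        for node in self.internal_nodes():
            below = node.leaf_names()
            side = frozenset(set(self.ids) - below) if ref in below else below
            if 2 <= len(side) <= n - 2:
                out[side] = node
        return out

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def _poisson(p: float) -> float:
    return -float(np.log(1.0 - min(p, MAX_P_DISTANCE)))


def distance_matrix(records: Sequence[ProteinRecord]) -> DistanceMatrix:
    """Poisson-corrected p-distances from pairwise global alignments.

    For each pair the sequences are globally aligned (BLOSUM62, affine gaps),
    p is the mismatch fraction over aligned non-gap columns, and
    d = -ln(1 - p) with p clamped at ``MAX_P_DISTANCE``.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    for r in records:
        if len(r) == 0:
            raise ValueError(f"empty sequence {r.id!r}")
    aligner = _protein_aligner()
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(records[i].residues, records[j].residues)[0]
            a, b = aln[0], aln[1]
            valid = mism = 0
            for x, y in zip(a, b):
                if x != "-" and y != "-":
                    valid += 1
                    if x != y:
                        mism += 1
            p = mism / valid if valid else 1.0
            d[i, j] = d[j, i] = _poisson(p)
    return DistanceMatrix(ids=tuple(r.id for r in records), d=d)


def nj_tree(matrix: DistanceMatrix) -> SupportTree:
    """Neighbor joining (Saitou–Nei Q-criterion), deterministic.

    Ties in the Q matrix are broken by the lowest (row, column) pair index;
    negative branch lengths are clamped to zero.  The returned tree is
    unrooted, stored with a trifurcating root at the last join.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    D = matrix.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in matrix.ids]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # upper triangle only; argmin is row-major -> lowest (i, j) on ties
        Q[np.tril_indices(r)] = np.inf
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        bi = dij / 2.0 + (R[ai] - R[aj]) / (2.0 * (r - 2))
        bj = dij - bi
        nodes[i].length = max(bi, 0.0)
        nodes[j].length = max(bj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # new row of distances
        new_row = np.zeros(D.shape[0] + 1)
        for ak, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    nodes[a].length = max((dab + dac - dbc) / 2.0, 0.0)
    nodes[b].length = max((dab + dbc - dac) / 2.0, 0.0)
    nodes[c].length = max((dac + dbc - dab) / 2.0, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return SupportTree(root=root, ids=matrix.ids)


# ---------------------------------------------------------------------------
# progressive multiple alignment (bootstrap needs columns)

def _consensus(rows: list[str]) -> str:
    """Per-column plurality residue (gaps excluded; ties alphabetical)."""
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            if ch != "-":
                counts[ch] = counts.get(ch, 0) + 1
        if counts:
            out.append(max(sorted(counts), key=lambda ch: counts[ch]))
        else:
            out.append("X")
    return "".join(out)


def _merge_blocks(block_a: list[str], block_b: list[str],
                  aligner: Align.PairwiseAligner) -> list[str]:
    """Merge two sub-alignments by aligning their consensus sequences."""
    ca, cb = _consensus(block_a), _consensus(block_b)
    aln = aligner.align(ca, cb)[0]
    ga, gb = aln[0], aln[1]  # gapped consensus strings, equal length
    rows_a = ["" for _ in block_a]
    rows_b = ["" for _ in block_b]
    ia = ib = 0
    for xa, xb in zip(ga, gb):
        if xa != "-":
            for k, row in enumerate(block_a):
                rows_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(block_a)):
                rows_a[k] += "-"
        if xb != "-":
            for k, row in enumerate(block_b):
                rows_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(block_b)):
                rows_b[k] += "-"
    return rows_a + rows_b


def progressive_alignment(
    records: Sequence[ProteinRecord],
    guide: SupportTree | None = None,
) -> tuple[tuple[str, ...], list[str]]:
    """Progressive multiple alignment over an NJ guide tree.

    Sub-alignments are merged bottom-up along the guide tree; each merge
    aligns the consensus sequences of the two blocks and projects the
    resulting gaps into every member row.  Returns (ids, aligned rows).
    """
    if guide is None:
        guide = nj_tree(distance_matrix(records))
    by_id = {r.id: r for r in records}

    def build(node: TreeNode, aligner: Align.PairwiseAligner) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [by_id[node.name].residues]  # type: ignore[list-item]
        ids, block = build(node.children[0], aligner)
        for child in node.children[1:]:
            cids, cblock = build(child, aligner)
            block = _merge_blocks(block, cblock, aligner)
            ids = ids + cids
        return ids, block

    ids, block = build(guide.root, _protein_aligner())
    return tuple(ids), block


def _msa_distmatrix(ids: tuple[str, ...], columns: np.ndarray) -> DistanceMatrix:
    """Poisson-corrected p-distances over alignment columns (chars array)."""
    n = len(ids)
    gap = columns == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~gap[i] & ~gap[j]
            nv = int(valid.sum())
            p = float((columns[i, valid] != columns[j, valid]).sum()) / nv if nv else 1.0
            d[i, j] = d[j, i] = _poisson(p)
    return DistanceMatrix(ids=ids, d=d)


def bootstrap_supports(
    records: Sequence[ProteinRecord],
    B: int = 100,
    seed: int = 0,
) -> SupportTree:
    """NJ tree with bootstrap supports from alignment-column resampling.

    A progressive multiple alignment is computed once; the main tree is NJ on
    Poisson-corrected distances from its full column set.  Each of the ``B``
    pseudo-replicates resamples columns with replacement, recomputes the
    distance matrix and NJ tree, and each internal edge's support is the
    number of replicates whose tree contains the same bipartition.
    Reproducible given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ids, rows = progressive_alignment(records)
    columns = np.array([list(r) for r in rows])
    main = nj_tree(_msa_distmatrix(ids, columns))
    biparts = main.bipartitions()
    counts = {bp: 0 for bp in biparts}
    rng = np.random.default_rng(seed)
    ncol = columns.shape[1]
    for _ in range(B):
        idx = rng.integers(0, ncol, size=ncol)
        rep = nj_tree(_msa_distmatrix(ids, columns[:, idx]))
        rep_biparts = set(rep.bipartitions())
        for bp in counts:
            if bp in rep_biparts:
                counts[bp] += 1
    for bp, node in biparts.items():
        node.support = counts[bp]
    return main


# ---------------------------------------------------------------------------
# clade grouping


@dataclass
class Group:
    index: int
    members: frozenset[str]
    support: int | None
    x4_identities: frozenset[str]
    subgroups: list["Group"] = field(default_factory=list)


@dataclass
class GroupPartition:
    """Partition of tree leaves into supported groups (and subgroups)."""

    groups: list[Group]
    assignment: dict[str, tuple[int, int | None]]  # id -> (group, subgroup|None)
    resolved_labels: dict[str, GroupLabel] | None = None

    @property
    def n_top_groups(self) -> int:
        return len(self.groups)

    @property
    def n_terminal_labels(self) -> int:
        return sum(len(g.subgroups) if g.subgroups else 1 for g in self.groups)

    def to_rows(self) -> list[dict[str, object]]:
        rows = []
        for rid, (g, sg) in sorted(self.assignment.items()):
            row: dict[str, object] = {
                "id": rid,
                "group": g,
                "subgroup": "" if sg is None else sg,
            }
            if self.resolved_labels is not None:
                row["label"] = self.resolved_labels[rid].value
            rows.append(row)
        return rows


def _x4_of(pattern: CoordinationPattern) -> str | None:
    site = pattern.site(SiteRole.X4)
    return site.residue if site.found else None


#: X4 identities that co-occur within one group (insertion groups hold two).
_X4_FAMILY = {"N": "NQ", "Q": "NQ", "S": "SH", "H": "SH"}

#: classifier labels -> top-level group family
_LABEL_FAMILY = {
    GroupLabel.G1: "1",
    GroupLabel.G2: "2",
    GroupLabel.G3: "3",
    GroupLabel.G4A: "4",
    GroupLabel.G4B: "4",
    GroupLabel.G5A: "5",
    GroupLabel.G5B: "5",
    GroupLabel.G6: "6",
}


def _member_keys(
    member: str,
    patterns: Mapping[str, CoordinationPattern],
    labels: Mapping[str, GroupLabel] | None,
) -> frozenset[str]:
    """Group-family keys a member is compatible with.

    From a classifier label when available (``UNRESOLVED_12`` is compatible
    with both group 1 and group 2); otherwise from the pattern signature
    (first-couple deletion flag, second-couple spacing, tandem His, X4
    family).
    """
    if labels is not None and member in labels:
        label = labels[member]
        if label is GroupLabel.UNRESOLVED_12:
            return frozenset({"1", "2"})
        if label in _LABEL_FAMILY:
            return frozenset({_LABEL_FAMILY[label]})
    p = patterns[member]
    x4 = _x4_of(p)
    sig = (
        "del" if (p.s1 is not None and p.s1 < 4) else "canon",
        p.s2,
        p.tandem_his_at_H3,
        _X4_FAMILY.get(x4 or "", x4),
    )
    return frozenset({f"sig:{sig}"})


def _homogeneous(
    clade: frozenset[str],
    patterns: Mapping[str, CoordinationPattern],
    labels: Mapping[str, GroupLabel] | None,
) -> bool:
    """True when every clade member is compatible with one shared group family."""
    common: frozenset[str] | None = None
    for m in sorted(clade):
        keys = _member_keys(m, patterns, labels)
        common = keys if common is None else common & keys
        if not common:
            return False
    return True


def extract_groups(
    tree: SupportTree,
    patterns: Mapping[str, CoordinationPattern],
    threshold: int = 95,
    subgroup_threshold: int = 100,
    labels: Mapping[str, GroupLabel] | None = None,
) -> GroupPartition:
    """Group tree leaves by strongly supported clades and coordination pattern.

    Following the taxonomy's joint criterion — clade support and the
    character at the coordination sites — groups are the maximal clades that
    both have bootstrap support strictly above ``threshold`` and are
    homogeneous in group family (one coordination signature, or one
    classifier label family when ``labels`` are given).  Leaves in no such
    clade form one residual group.  A group whose members carry two or more
    distinct residues at the fourth coordination site is split into
    subgroups at the internal edges with support at least
    ``subgroup_threshold`` that separate the identities; leftover members
    are grouped by their own X4 residue.

    When per-sequence classifier ``labels`` are given, members labeled
    ``UNRESOLVED_12`` are resolved to G1/G2 by co-membership with
    motif-resolved members of their group, and the resolved labels are
    attached to the partition.
    """
    leaf_ids = set(tree.ids)
    missing = leaf_ids - set(patterns)
    if missing:
        raise ValueError(f"leaves without a coordination pattern: {sorted(missing)}")

    # candidate clades: the smaller side of each supported bipartition
    def clade_side(bp: frozenset[str]) -> frozenset[str]:
        other = frozenset(leaf_ids - bp)
        if len(bp) != len(other):
            return bp if len(bp) < len(other) else other
        return min(bp, other, key=lambda s: tuple(sorted(s)))

    supported = [
        (clade_side(bp), node.support)
        for bp, node in tree.bipartitions().items()
        if node.support is not None and node.support > threshold
        and _homogeneous(clade_side(bp), patterns, labels)
    ]
    # maximal clades (laminar family: keep those not inside a bigger one)
    supported.sort(key=lambda t: (-len(t[0]), tuple(sorted(t[0]))))
    maximal: list[tuple[frozenset[str], int]] = []
    for clade, sup in supported:
        if not any(clade <= big for big, _ in maximal):
            maximal.append((clade, sup))

    groups: list[Group] = []
    assigned: set[str] = set()
    for idx, (clade, sup) in enumerate(maximal, start=1):
        x4s = frozenset(x for m in clade if (x := _x4_of(patterns[m])) is not None)
        groups.append(Group(index=idx, members=clade, support=sup, x4_identities=x4s))
        assigned |= clade
    rest = frozenset(leaf_ids - assigned)
    if rest:
        x4s = frozenset(x for m in rest if (x := _x4_of(patterns[m])) is not None)
        groups.append(Group(index=len(groups) + 1, members=rest, support=None,
                            x4_identities=x4s))

    # subgroup splitting inside mixed-X4 groups
    strong = [
        (clade_side(bp), node.support)
        for bp, node in tree.bipartitions().items()
        if node.support is not None and node.support >= subgroup_threshold
    ]
    assignment: dict[str, tuple[int, int | None]] = {}
    for group in groups:
        if len(group.x4_identities) < 2:
            for m in group.members:
                assignment[m] = (group.index, None)
            continue
        candidates = [
            c for c, s in strong
            if c < group.members
            and len({x for m in c if (x := _x4_of(patterns[m])) is not None}) <= 1
        ]
        candidates.sort(key=lambda c: (-len(c), tuple(sorted(c))))
        taken: set[str] = set()
        sub_sets: list[set[str]] = []
        for c in candidates:
            if c & taken:
                continue
            sub_sets.append(set(c))
            taken |= c
        # leftovers grouped by their own X4 residue
        leftovers: dict[str | None, set[str]] = {}
        for m in sorted(group.members - taken):
            leftovers.setdefault(_x4_of(patterns[m]), set()).add(m)
        sub_sets.extend(leftovers[k] for k in sorted(leftovers, key=str))
        # merge sub-sets with identical X4 identity
        by_x4: dict[tuple[str, ...], set[str]] = {}
        for s in sub_sets:
            key = tuple(sorted({x for m in s if (x := _x4_of(patterns[m])) is not None}))
            by_x4.setdefault(key, set()).update(s)
        for sub_idx, key in enumerate(sorted(by_x4), start=1):
            members = frozenset(by_x4[key])
            group.subgroups.append(
                Group(index=sub_idx, members=members, support=None,
                      x4_identities=frozenset(key))
            )
            for m in members:
                assignment[m] = (group.index, sub_idx)

    resolved: dict[str, GroupLabel] | None = None
    if labels is not None:
        resolved = dict(labels)
        for group in groups:
            present = {labels[m] for m in group.members if m in labels}
            target: GroupLabel | None = None
            if GroupLabel.G1 in present and GroupLabel.G2 not in present:
                target = GroupLabel.G1
            elif GroupLabel.G2 in present and GroupLabel.G1 not in present:
                target = GroupLabel.G2
            if target is not None:
                for m in group.members:
                    if resolved.get(m) is GroupLabel.UNRESOLVED_12:
                        resolved[m] = target
    return GroupPartition(groups=groups, assignment=assignment,
                          resolved_labels=resolved)
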