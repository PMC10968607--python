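"""Distance matrices, neighbor joining, bootstrap supports, clade grouping."""

from __future__ import annotations

import numpy as np
import pytest

from diatomlox import (
    DistanceMatrix,
    GroupLabel,
    ProteinRecord,
    bootstrap_supports,
    classify_pattern,
    distance_matrix,
    extract_groups,
    nj_tree,
    scan_coordination,
)

AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _block_records(rng, n_blocks=2, per_block=4, length=150, within=8):
    """Families of near-identical sequences on unrelated backgrounds."""
    records = []
    for b in range(n_blocks):
        base = rng.choice(AMINO, length)
        for m in range(per_block):
            s = base.copy()
            idx = rng.choice(length, within, replace=False)
            s[idx] = rng.choice(AMINO, within)
            records.append(ProteinRecord(id=f"B{b}_{m}", residues="".join(s)))
    return records


# ---------------------------------------------------------------------------
# distances


class TestDistanceMatrix:
    def test_identical_sequences_have_zero_distance(self):
        recs = [ProteinRecord(id=f"r{k}", residues="MKVLHHA" * 20) for k in range(3)]
        m = distance_matrix(recs)
        assert np.allclose(m.d, 0.0)

    def test_poisson_correction_closed_form(self):
        # two length-100 sequences differing at exactly 10 positions, no gaps
        base = list("ACDEFGHIKL" * 10)
        other = base.copy()
        for i in range(0, 100, 10):  # 10 evenly spread mismatches
            other[i] = "W" if base[i] != "W" else "Y"
        recs = [
            ProteinRecord(id="a", residues="".join(base)),
            ProteinRecord(id="b", residues="".join(other)),
            ProteinRecord(id="c", residues="".join(base)),
        ]
        m = distance_matrix(recs)
        assert m.d[0, 1] == pytest.approx(-np.log(0.90), abs=1e-9)
        assert m.d[0, 2] == 0.0

    def test_saturated_distance_is_clamped(self):
        rng = np.random.default_rng(0)
        recs = [
            ProteinRecord(id=f"r{k}", residues="".join(rng.choice(AMINO, 200)))
            for k in range(3)
        ]
        m = distance_matrix(recs)
        assert np.all(m.d[np.triu_indices(3, 1)] <= -np.log(0.05) + 1e-9)

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=("a", "b"), d=np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="non-finite"):
            DistanceMatrix(ids=("a", "b"), d=np.array([[0.0, np.inf], [np.inf, 0.0]]))


# ---------------------------------------------------------------------------
# neighbor joining


def _random_additive(rng, n_taxa):
    """A random binary tree and its additive leaf distance matrix.

    The generating topology and path distances are the independent truth the
    NJ result is checked against.
    """
    ids = [f"t{k}" for k in range(n_taxa)]
    # start from a star over three leaves, attach remaining leaves to random edges
    nodes = {i: {"parent": None} for i in ids}
    # represent as edge list on an anonymous graph
    import itertools

    next_internal = 0
    edges = []  # (u, v, length)

    def new_internal():
        nonlocal next_internal
        next_internal += 1
        return f"i{next_internal}"

    center = new_internal()
    for leaf in ids[:3]:
        edges.append([center, leaf, rng.uniform(0.1, 1.0)])
    for leaf in ids[3:]:
        k = rng.integers(len(edges))
        u, v, w = edges.pop(k)
        mid = new_internal()
        split = rng.uniform(0.2, 0.8)
        edges.append([u, mid, w * split])
        edges.append([mid, v, w * (1 - split)])
        edges.append([mid, leaf, rng.uniform(0.1, 1.0)])

    # path distances by BFS over the edge list
    import collections

    adj = collections.defaultdict(list)
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))

    def dist_from(src):
        seen = {src: 0.0}
        queue = collections.deque([src])
        while queue:
            x = queue.popleft()
            for y, w in adj[x]:
                if y not in seen:
                    seen[y] = seen[x] + w
                    queue.append(y)
        return seen

    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(ids):
        da = dist_from(a)
        for j, b in enumerate(ids):
            d[i, j] = da[b]
    d = (d + d.T) / 2.0  # BFS summation order leaves tiny float asymmetry
    np.fill_diagonal(d, 0.0)

    # true bipartitions: for each internal edge, the leaf set on one side
    def side(u, v):
        seen = {u}
        queue = collections.deque([u])
        while queue:
            x = queue.popleft()
            for y, _ in adj[x]:
                if y != v and y not in seen and not (x == u and y == v):
                    seen.add(y)
                    queue.append(y)
        return frozenset(x for x in seen if x in ids)

    ref = ids[0]
    true_biparts = set()
    for u, v, _ in edges:
        if u.startswith("i") and v.startswith("i"):
            s = side(u, v)
            s = frozenset(set(ids) - s) if ref in s else s
            if 2 <= len(s) <= n_taxa - 2:
                true_biparts.add(s)
    return DistanceMatrix(ids=tuple(ids), d=d), true_biparts


class TestNeighborJoining:
    def test_three_taxa_closed_form_branch_lengths(self):
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(DistanceMatrix(ids=("a", "b", "c"), d=d))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["a"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["b"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lengths["c"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_four_taxon_additive_topology_recovered(self):
        # additive distances on ((A,B),(C,D)); the four-point condition picks
        # the AB|CD split, which is the only bipartition NJ may output
        d = np.array(
            [
                [0.0, 0.3, 1.0, 1.1],
                [0.3, 0.0, 1.1, 1.2],
                [1.0, 1.1, 0.0, 0.3],
                [1.1, 1.2, 0.3, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(ids=("A", "B", "C", "D"), d=d))
        assert set(tree.bipartitions()) == {frozenset({"C", "D"})}

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrices_recover_generating_topology(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        matrix, true_biparts = _random_additive(rng, n)
        tree = nj_tree(matrix)
        assert set(tree.bipartitions()) == true_biparts

    def test_agrees_with_independent_nj_implementation(self):
        """Cross-check clade structure against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        matrix, true_biparts = _random_additive(rng, 7)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(matrix.d, ids=matrix.ids))
        ref = matrix.ids[0]
        sk_biparts = set()
        for node in sk_tree.non_tips():
            s = frozenset(t.name for t in node.tips())
            s = frozenset(set(matrix.ids) - s) if ref in s else s
            if 2 <= len(s) <= len(matrix.ids) - 2:
                sk_biparts.add(s)
        assert set(nj_tree(matrix).bipartitions()) == sk_biparts

    def test_rejects_tiny_matrices(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(ids=("a", "b"), d=np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# bootstrap


def _block_support(tree, block: frozenset[str]) -> int | None:
    """Support of the block|rest bipartition, whichever side keys it."""
    complement = frozenset(set(tree.ids) - block)
    biparts = tree.bipartitions()
    node = biparts.get(block) or biparts.get(complement)
    return None if node is None else node.support


class TestBootstrap:
    @pytest.mark.parametrize("seed", range(5))
    def test_two_block_fixture_block_support_high(self, seed):
        rng = np.random.default_rng(100 + seed)
        records = _block_records(rng)
        tree = bootstrap_supports(records, B=100, seed=seed)
        block = frozenset(f"B1_{m}" for m in range(4))
        support = _block_support(tree, block)
        assert support is not None and support >= 95

    def test_single_replicate_supports_binary(self):
        rng = np.random.default_rng(4)
        records = _block_records(rng)
        tree = bootstrap_supports(records, B=1, seed=0)
        supports = [n.support for n in tree.internal_nodes() if n.support is not None]
        assert supports and set(supports) <= {0, 1}

    def test_record_order_permutation_keeps_block_support(self):
        rng = np.random.default_rng(7)
        records = _block_records(rng)
        perm = [records[k] for k in np.random.default_rng(1).permutation(len(records))]
        block = frozenset(f"B1_{m}" for m in range(4))
        for rec_set in (records, perm):
            tree = bootstrap_supports(rec_set, B=50, seed=5)
            support = _block_support(tree, block)
            assert support is not None and support >= 47

    def test_rejects_nonpositive_replicates(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            bootstrap_supports(_block_records(rng), B=0, seed=0)


# ---------------------------------------------------------------------------
# grouping


class TestExtractGroups:
    def test_low_support_everywhere_gives_single_group(self, seq_fixture):
        records = seq_fixture.records
        patterns = {
            r.id: scan_coordination(r, seq_fixture.anchors) for r in records
        }
        tree = bootstrap_supports(records[:6], B=5, seed=0)
        # force all supports below threshold
        for node in tree.internal_nodes():
            if node.support is not None:
                node.support = 0
        part = extract_groups(tree, patterns, threshold=95)
        assert part.n_top_groups == 1
        assert set().union(*(g.members for g in part.groups)) == set(tree.ids)

    def test_family_fixture_recovers_six_groups_eight_labels(self, family_fixture):
        fx = family_fixture
        patterns = {r.id: scan_coordination(r, fx.anchors) for r in fx.records}
        labels = {
            r.id: classify_pattern(patterns[r.id], fx.motifs, r)
            for r in fx.records
        }
        tree = bootstrap_supports(fx.records, B=100, seed=11)
        part = extract_groups(tree, patterns, threshold=95, labels=labels)
        assert part.n_top_groups == 6
        assert part.n_terminal_labels == 8
        # mixed-X4 groups were split along the subgroup truth
        for group in part.groups:
            for sub in group.subgroups:
                truth_labels = {fx.truth[m].label for m in sub.members}
                assert len(truth_labels) == 1

    def test_unresolved_members_inherit_clade_label(self, family_fixture):
        fx = family_fixture
        patterns = {r.id: scan_coordination(r, fx.anchors) for r in fx.records}
        labels = {
            r.id: classify_pattern(patterns[r.id], fx.motifs, r)
            for r in fx.records
        }
        # pretend motifs were unavailable for two group-1 members
        g1 = [r.id for r in fx.records if fx.truth[r.id].label is GroupLabel.G1]
        for rid in g1[:2]:
            labels[rid] = GroupLabel.UNRESOLVED_12
        tree = bootstrap_supports(fx.records, B=100, seed=11)
        part = extract_groups(tree, patterns, threshold=95, labels=labels)
        assert part.resolved_labels is not None
        for rid in g1[:2]:
            assert part.resolved_labels[rid] is GroupLabel.G1

    def test_leaf_without_pattern_errors(self, seq_fixture):
        records = seq_fixture.records[:4]
        tree = bootstrap_supports(records, B=2, seed=0)
        with pytest.raises(ValueError, match="without a coordination pattern"):
            extract_groups(tree, {}, threshold=95)
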