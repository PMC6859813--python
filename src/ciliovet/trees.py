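"""Phylogenetic tree container and clade queries.

A thin wrapper over a dendropy tree providing the handful of operations the
vetting and placement stages need: Newick round-trips, outgroup rooting,
maximal same-label clades, path distances and bipartition comparisons.
Leaf labels are the sequence (or taxon) identifiers; metadata lives outside
the tree and is joined by label.
"""
from __future__ import annotations

from typing import Callable, Iterable, Optional

import dendropy


class TreeError(ValueError):
    pass


def _load(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick: {e}") from e


class PhyloTree:
    """(Un)rooted tree with branch lengths, keyed by leaf labels."""

    def __init__(self, tree: dendropy.Tree):
        self.t = tree

    # -- construction / io -------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, taxa: Optional[Iterable[str]] = None) -> "PhyloTree":
        """Parse Newick; if ``taxa`` given, every leaf label must be in it."""
        tree = _load(newick)
        pt = cls(tree)
        if taxa is not None:
            known = set(taxa)
            missing = [l for l in pt.leaf_labels() if l not in known]
            if missing:
                raise TreeError(f"leaf labels not in metadata: {sorted(missing)}")
        return pt

    def to_newick(self) -> str:
        return (
            self.t.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
            + ("" if self.t.as_string(schema="newick").strip().endswith(";") else ";")
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.t.clone(depth=1))

    # -- basic queries -----------------------------------------------------
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.t.leaf_node_iter()]

    def n_leaves(self) -> int:
        return sum(1 for _ in self.t.leaf_node_iter())

    def _leaf(self, label: str):
        for lf in self.t.leaf_node_iter():
            if lf.taxon.label == label:
                return lf
        raise TreeError(f"no leaf labelled {label!r}")

    def branch_lengths(self) -> dict:
        """Map leaf-set-below-edge (frozenset) -> branch length, pendant edges by label."""
        out = {}
        for nd in self.t.preorder_node_iter():
            if nd.parent_node is None:
                continue
            below = frozenset(l.taxon.label for l in nd.leaf_iter())
            out[below] = nd.edge.length
        return out

    # -- bipartitions & topology comparison --------------------------------
    def bipartitions(self) -> set:
        """Non-trivial splits as frozensets, normalised to exclude the
        lexicographically smallest leaf label."""
        labels = sorted(self.leaf_labels())
        ref = labels[0]
        full = set(labels)
        n = len(labels)
        out = set()
        for nd in self.t.preorder_internal_node_iter():
            if nd.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in nd.leaf_iter())
            if ref in side:
                side = frozenset(full - side)
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return out

    def same_topology(self, other: "PhyloTree") -> bool:
        """Unrooted topological identity (equal leaf sets and splits)."""
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            return False
        return self.bipartitions() == other.bipartitions()

    def has_clade(self, labels: Iterable[str]) -> bool:
        """True if ``labels`` form a split of the unrooted tree (clade under
        some rooting outside the set)."""
        want = frozenset(labels)
        full = frozenset(self.leaf_labels())
        if not want <= full:
            return False
        if len(want) <= 1 or len(full - want) <= 1:
            return True
        ref = min(full)
        norm = want if ref not in want else full - want
        return norm in self.bipartitions()

    # -- distances ---------------------------------------------------------
    def leaf_distance_matrix(self) -> tuple[list[str], "object"]:
        """(labels, numpy matrix) of patristic distances (branch-length sums)."""
        import numpy as np

        labels = sorted(self.leaf_labels())
        idx = {l: i for i, l in enumerate(labels)}
        pdm = self.t.phylogenetic_distance_matrix()
        D = np.zeros((len(labels), len(labels)))
        for t1 in pdm.taxon_iter():
            for t2 in pdm.taxon_iter():
                D[idx[t1.label], idx[t2.label]] = pdm.patristic_distance(t1, t2)
        return labels, D

    def node_to_leaf_paths(self, node) -> dict:
        """From a node, (edge_count, branch_length_sum) to every leaf."""
        # undirected BFS over the tree graph
        adj: dict = {}

        def add(a, b, w):
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))

        for nd in self.t.preorder_node_iter():
            if nd.parent_node is not None:
                add(nd.parent_node, nd, nd.edge.length or 0.0)
        dist = {node: (0, 0.0)}
        stack = [node]
        while stack:
            cur = stack.pop()
            e, w = dist[cur]
            for nb, ew in adj.get(cur, []):
                if nb not in dist:
                    dist[nb] = (e + 1, w + ew)
                    stack.append(nb)
        return {
            nd.taxon.label: d
            for nd, d in dist.items()
            if nd.is_leaf() and nd.taxon is not None
        }

    # -- rooting -----------------------------------------------------------
    def root_with_outgroup(self, outgroup_labels: Iterable[str]) -> "PhyloTree":
        """Root on the edge best separating the outgroup from the rest.

        If some outgroup-only clade exists, the largest such clade's
        subtending edge is used; otherwise the edge whose induced split
        disagrees least with the outgroup/ingroup partition (ties broken by
        the smaller outgroup-side clade). A tree that is all-outgroup (or
        has no outgroup leaf among its labels) cannot be polarised this way
        and raises.
        """
        og = set(outgroup_labels) & set(self.leaf_labels())
        all_lbl = set(self.leaf_labels())
        if not og:
            raise TreeError("no outgroup leaf present")
        if og == all_lbl:
            # degenerate: midpoint-root and flag by raising? spec: root midpoint.
            t = self.copy()
            t.t.reroot_at_midpoint(update_bipartitions=False)
            return t
        t = self.copy()
        best = None  # (mismatch, side_size, order, node)
        for i, nd in enumerate(t.t.preorder_node_iter()):
            if nd.parent_node is None:
                continue
            side = {l.taxon.label for l in nd.leaf_iter()}
            # disagreement of split {side | rest} with {outgroup | rest}:
            # leaves on the wrong side, for the better of the two orientations
            mism = min(len(side ^ og), len((all_lbl - side) ^ og))
            key = (mism, min(len(side), len(all_lbl - side)), i)
            if best is None or key < best[0]:
                best = (key, nd)
        node = best[1]
        ln = node.edge.length
        if ln is None:
            t.t.reroot_at_edge(node.edge, update_bipartitions=False)
        else:
            t.t.reroot_at_edge(
                node.edge, length1=ln / 2.0, length2=ln / 2.0, update_bipartitions=False
            )
        t.t.is_rooted = True
        return t

    # -- clades ------------------------------------------------------------
    def maximal_label_clades(
        self, predicate: Callable[[str], bool]
    ) -> list[list[str]]:
        """All maximal clades whose every leaf satisfies ``predicate``.

        The tree must be rooted (interpretation of "clade" is rooted).
        Maximality: the parent clade contains at least one non-satisfying
        leaf (or the clade is the whole tree).
        """
        result: list[list[str]] = []

        def walk(node) -> bool:
            """Return True iff every leaf under node satisfies predicate."""
            if node.is_leaf():
                return bool(predicate(node.taxon.label))
            flags = [walk(ch) for ch in node.child_nodes()]
            return all(flags)

        # post-order with memo to avoid exponential: compute once
        ok: dict = {}
        for nd in self.t.postorder_node_iter():
            if nd.is_leaf():
                ok[nd] = bool(predicate(nd.taxon.label))
            else:
                ok[nd] = all(ok[ch] for ch in nd.child_nodes())
        for nd in self.t.preorder_node_iter():
            if ok[nd] and (nd.parent_node is None or not ok[nd.parent_node]):
                result.append(sorted(l.taxon.label for l in nd.leaf_iter()))
        return result

    def mrca(self, labels: Iterable[str]):
        import warnings

        taxa = [self._leaf(l).taxon for l in labels]
        with warnings.catch_warnings():
            # dendropy warns on unrooted trees; treating the seed node as
            # root is exactly the intended semantics here
            warnings.simplefilter("ignore", UserWarning)
            return self.t.mrca(taxa=taxa)

    def clade_leaves(self, node) -> list[str]:
        return sorted(l.taxon.label for l in node.leaf_iter())

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Restrict to a label subset (suppresses unifurcations)."""
        keep = set(labels)
        t = self.copy()
        t.t.retain_taxa_with_labels(list(keep))
        return t


def regraft(
    tree: PhyloTree,
    clade_labels: Iterable[str],
    sister_labels: Iterable[str],
    stem_length: float = 0.1,
) -> PhyloTree:
    """Move a clade so it becomes sister to another group (hypothesis-tree
    construction). The clade is pruned out and re-inserted on the edge above
    the MRCA of ``sister_labels`` in the reduced tree; inserted edges get
    ``stem_length`` (branch lengths are refit downstream anyway)."""
    clade = sorted(set(clade_labels))
    rest = [l for l in tree.leaf_labels() if l not in set(clade)]
    sisters = [l for l in sister_labels if l in rest]
    if not sisters:
        raise TreeError("sister group is empty after pruning")
    sub = tree.prune_to(clade) if len(clade) > 1 else None
    sub_str = (
        sub.to_newick().rstrip(";").rstrip()
        if sub is not None
        else f"{clade[0]}:{stem_length!r}"
    )
    if sub is not None:
        # strip any trailing root length, keep the subtree parenthetical
        s = sub.to_newick().rstrip(";")
        sub_str = f"{s}:{stem_length!r}" if not s.endswith(")") else f"{s}:{stem_length!r}"
    host = tree.prune_to(rest)
    target = host.mrca(sisters) if len(sisters) > 1 else host._leaf(sisters[0])
    # insert a new node on the edge above target
    import dendropy

    parent = target.parent_node
    graft = dendropy.Tree.get(
        data=sub_str + ";", schema="newick", preserve_underscores=True,
        taxon_namespace=host.t.taxon_namespace,
    ).seed_node
    newn = dendropy.Node()
    if parent is None:
        # target is the seed node: new root above it
        newn.add_child(target)
        newn.add_child(graft)
        host.t.seed_node = newn
    else:
        el = target.edge.length or stem_length
        parent.remove_child(target)
        parent.add_child(newn)
        newn.edge.length = el / 2.0
        target.edge.length = el / 2.0
        newn.add_child(target)
        newn.add_child(graft)
    graft.edge.length = stem_length
    host.t.update_bipartitions(suppress_unifurcations=True)
    return PhyloTree.from_newick(host.t.as_string(schema="newick", suppress_rooting=True))
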