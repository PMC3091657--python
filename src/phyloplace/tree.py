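"""Reference tree with stable branch identifiers.

The tree is stored exactly as parsed (rooted if the newick root is a
bifurcation, otherwise with a multifurcating "root" that merely anchors
the traversal).  Every edge — identified by its child node — carries an
integer branch id assigned by a postorder traversal of the child arrays
in parsed order, so a leaf's pendant edge is always numbered before the
edges of its ancestors and ids are reproducible across runs, platforms
and serialization.

Placement operates on the *unrooted view*: for a tree whose root has
exactly two children the two root-adjacent edges form a single
placement branch (reversible models cannot resolve the root), so a
rooted binary tree over L leaves carries 2L-2 edges but 2L-3 placement
branches; reporting maps placements back onto the stored rooted edges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "ReferenceTree",
    "PlacementBranch",
    "parse_newick",
    "write_newick",
]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "length", "children", "parent", "edge_id", "index")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = length  # length of the edge to the parent
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.edge_id: int | None = None  # branch id of the edge to the parent
        self.index: int | None = None  # postorder node index

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self):
        stack = [(self, iter(self.children))]
        while stack:
            node, it = stack[-1]
            child = next(it, None)
            if child is None:
                stack.pop()
                yield node
            else:
                stack.append((child, iter(child.children)))


@dataclass(frozen=True)
class PlacementBranch:
    """One branch of the unrooted placement view.

    ``edges`` holds the underlying rooted-tree edge ids — one entry for
    an ordinary edge, two for the merged root-adjacent pair.  ``head``
    is the node at the distal (child) end from which insertion
    positions are measured.
    """

    branch_id: int
    edges: tuple[int, ...]
    length: float
    head: Node
    tail: Node

    def to_edge_coordinates(self, distal: float, edge_lengths: dict[int, float]) -> tuple[int, float]:
        """Map a position ``distal`` from ``head`` onto a rooted edge.

        Returns (edge id, distance from that edge's child end), the
        coordinates used for rooted reporting and jplace output.
        """
        if len(self.edges) == 1:
            return self.edges[0], distal
        e_head, e_tail = self.edges
        l_head = edge_lengths[e_head]
        if distal <= l_head:
            return e_head, distal
        l_tail = edge_lengths[e_tail]
        return e_tail, max(l_tail - (distal - l_head), 0.0)


class ReferenceTree:
    """Phylogeny with branch lengths and stable integer branch ids."""

    def __init__(self, root: Node):
        self.root = root
        self._index()

    # ------------------------------------------------------------------
    def _index(self) -> None:
        self.nodes: list[Node] = []
        self.edge_nodes: list[Node] = []  # edge id -> child node
        eid = 0
        for i, node in enumerate(self.root.postorder()):
            node.index = i
            self.nodes.append(node)
            if node.parent is not None:
                node.edge_id = eid
                self.edge_nodes.append(node)
                eid += 1
            else:
                node.edge_id = None
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.nodes:
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)
            if node.parent is not None:
                if not (node.length >= 0.0) or node.length != node.length:
                    raise TreeError(
                        f"negative or non-finite branch length {node.length!r} "
                        f"on edge to {node.label or 'internal node'}"
                    )
                if node.length == float("inf"):
                    raise TreeError("infinite branch length")

    # ------------------------------------------------------------------
    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_edges(self) -> int:
        return len(self.edge_nodes)

    @property
    def is_rooted_binary(self) -> bool:
        return len(self.root.children) == 2

    @property
    def n_placement_branches(self) -> int:
        return self.n_edges - (1 if self.is_rooted_binary else 0)

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.edge_nodes)

    def edge_lengths(self) -> dict[int, float]:
        return {n.edge_id: n.length for n in self.edge_nodes}

    def copy(self) -> "ReferenceTree":
        return parse_newick(write_newick(self, digits=17))

    # ------------------------------------------------------------------
    def placement_branches(self) -> list[PlacementBranch]:
        """Branches of the unrooted view, in stable order.

        Ordinary edges keep their edge id as branch id position; for a
        degree-2 root the two root edges merge into one branch carrying
        the smaller of the two edge ids, with the first root child as
        the distal (head) end.
        """
        branches: list[PlacementBranch] = []
        if self.is_rooted_binary:
            c1, c2 = self.root.children
            merged = PlacementBranch(
                branch_id=min(c1.edge_id, c2.edge_id),
                edges=(c1.edge_id, c2.edge_id),
                length=c1.length + c2.length,
                head=c1,
                tail=c2,
            )
            for node in self.edge_nodes:
                if node is c1:
                    branches.append(merged)
                elif node is c2:
                    continue
                else:
                    branches.append(
                        PlacementBranch(node.edge_id, (node.edge_id,), node.length, node, node.parent)
                    )
        else:
            for node in self.edge_nodes:
                branches.append(
                    PlacementBranch(node.edge_id, (node.edge_id,), node.length, node, node.parent)
                )
        return branches

    # ------------------------------------------------------------------
    def _unrooted_adjacency(self) -> dict[int, set[int]]:
        """Node-index adjacency of the unrooted view (degree-2 root suppressed)."""
        adj: dict[int, set[int]] = {n.index: set() for n in self.nodes}
        for node in self.edge_nodes:
            adj[node.index].add(node.parent.index)
            adj[node.parent.index].add(node.index)
        if self.is_rooted_binary:
            r = self.root.index
            a, b = (c.index for c in self.root.children)
            adj[a].discard(r)
            adj[b].discard(r)
            adj[a].add(b)
            adj[b].add(a)
            del adj[r]
        return adj

    def node_distance(self, branch_a: int, branch_b: int) -> int:
        """Number of nodes strictly between two placement branches.

        0 for the same branch, 1 for branches sharing an endpoint, and
        in general the number of nodes on the unrooted-view path
        connecting the two branches.  Edge ids belonging to the same
        merged root pair count as the same branch.
        """
        lookup = {}
        for br in self.placement_branches():
            for e in br.edges:
                lookup[e] = br
        try:
            ba, bb = lookup[branch_a], lookup[branch_b]
        except KeyError as exc:
            raise TreeError(f"unknown branch id {exc.args[0]}") from None
        if ba.branch_id == bb.branch_id:
            return 0
        adj = self._unrooted_adjacency()
        # in the unrooted view a branch's ends are head/tail; for the
        # merged root pair these are the two root children, and ordinary
        # branches never touch the suppressed root
        a1, a2 = ba.head.index, ba.tail.index
        b1, b2 = bb.head.index, bb.tail.index
        targets = {b1, b2}
        # BFS from both endpoints of branch a over nodes, stopping at b's ends
        from collections import deque

        best = None
        for start in (a1, a2):
            dist = {start: 1}  # path node count including start
            dq = deque([start])
            while dq:
                u = dq.popleft()
                if u in targets:
                    cand = dist[u]
                    best = cand if best is None else min(best, cand)
                    continue
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        dq.append(v)
        if best is None:
            raise TreeError("branches are not connected")  # pragma: no cover
        return best


# ----------------------------------------------------------------------
# newick I/O (via dendropy, wrapped for validation and stable precision)


def _from_dendropy(dnode: dendropy.Node) -> Node:
    label = None
    if dnode.is_leaf():
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        if label is None:
            raise TreeError("leaf with empty label")
        label = label.replace(" ", "_")
    node = Node(label=label, length=0.0)
    if dnode.parent_node is not None:
        if dnode.edge.length is None:
            raise TreeError(f"missing branch length on edge to {label or 'internal node'}")
        node.length = float(dnode.edge.length)
    for child in dnode.child_nodes():
        node.add(_from_dendropy(child))
    return node


def parse_newick(text: str) -> ReferenceTree:
    """Parse a newick string with branch lengths into a ReferenceTree."""
    if not text or not text.strip():
        raise TreeError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    if len(root.children) < 2:
        raise TreeError("tree must have at least two children at the root")
    return ReferenceTree(root)


def _write_node(node: Node, out: io.StringIO, digits: int) -> None:
    if node.is_leaf:
        out.write(node.label)
    else:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _write_node(child, out, digits)
        out.write(")")
    if node.parent is not None:
        out.write(f":{node.length:.{digits}g}")


def write_newick(tree: ReferenceTree, digits: int = 12) -> str:
    """Serialize with >= 10 significant digits so round trips are stable."""
    if digits < 10:
        raise TreeError("branch lengths must be printed with at least 10 significant digits")
    out = io.StringIO()
    _write_node(tree.root, out, digits)
    out.write(";")
    return out.getvalue()


def orient_placement_view(branches: list[PlacementBranch]):
    """Orient the unrooted view from a fixed internal anchor node.

    Returns (anchor, postorder node indices, children map, parent-branch
    map); the anchor is the smallest-index internal node, so the
    orientation is a pure function of the branch list.
    """
    adj: dict[int, list[tuple[int, PlacementBranch]]] = {}
    for b in branches:
        adj.setdefault(b.head.index, []).append((b.tail.index, b))
        adj.setdefault(b.tail.index, []).append((b.head.index, b))
    internal = [n for n, nb in adj.items() if len(nb) >= 2]
    # two-leaf trees have no internal node; anchor at a leaf instead
    root = min(internal) if internal else min(adj)
    parent: dict[int, int] = {root: -1}
    parent_branch: dict[int, PlacementBranch] = {}
    children: dict[int, list[tuple[int, PlacementBranch]]] = {n: [] for n in adj}
    order = []
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for v, b in sorted(adj[u], key=lambda vb: vb[1].branch_id):
            if v not in parent:
                parent[v] = u
                parent_branch[v] = b
                children[u].append((v, b))
                stack.append(v)
    return root, order[::-1], children, parent_branch


# ----------------------------------------------------------------------
# pruning (leave-one-out surgery)


def _prune_rec(node: Node, drop: set[str], marks: list[Node], survivors: list[Node]) -> Node | None:
    if node.is_leaf:
        if node.label in drop:
            return None
        return Node(node.label, node.length)
    kids = []
    lost = False
    for c in node.children:
        nc = _prune_rec(c, drop, marks, survivors)
        if nc is None:
            lost = True
        else:
            kids.append(nc)
    if not kids:
        return None
    if len(kids) == 1 and node.parent is not None:
        # suppress the degree-2 node, merging the two edge segments;
        # the attachment point (if any) now lies inside the merged edge
        child = kids[0]
        child.parent = None
        child.length += node.length
        if lost:
            marks.append(child)
        return child
    n = Node(None, node.length)
    for k in kids:
        n.add(k)
    if lost:
        survivors.append(n)
    return n


def prune_leaves(tree: ReferenceTree, labels) -> tuple[ReferenceTree, int | None]:
    """Remove leaves, suppress degree-2 nodes, and locate the attachment.

    Returns the reduced tree and the branch id (in the reduced tree's
    numbering, placement-view id) of the branch onto which the removed
    material's attachment point collapsed — the "true branch" of a
    leave-one-out experiment.  None when the attachment is ambiguous
    (scattered leaf sets on multifurcating trees).
    """
    drop = set(labels)
    have = set(tree.leaf_labels)
    missing = drop - have
    if missing:
        raise TreeError(f"cannot prune unknown leaves: {sorted(missing)}")
    if len(have - drop) < 3:
        raise TreeError("pruning would leave fewer than 3 leaves")
    marks: list[Node] = []
    survivors: list[Node] = []
    new_root = _prune_rec(tree.root, drop, marks, survivors)
    assert new_root is not None
    root_lost = False
    while len(new_root.children) == 1:
        # dangling root stub: the remaining child becomes the new root
        new_root = new_root.children[0]
        new_root.parent = None
        new_root.length = 0.0
        root_lost = True
    reduced = ReferenceTree(new_root)
    unique_marks = list({id(m): m for m in marks}.values())
    marked: Node | None = unique_marks[0] if len(unique_marks) == 1 else None
    if marked is None and not marks:
        for s in survivors:
            if s.parent is None and len(s.children) == 2:
                # attachment was at a root that is now a bifurcation:
                # the point lies on the merged root branch
                marked = s.children[0]
                break
        if marked is None and root_lost and not survivors:
            marked = new_root.children[0]
    if marked is None:
        return reduced, None
    if reduced.is_rooted_binary and marked.parent is reduced.root:
        c1, c2 = reduced.root.children
        return reduced, min(c1.edge_id, c2.edge_id)
    return reduced, marked.edge_id


def clade_leaf_labels(tree: ReferenceTree, leaf_label: str, depth: int) -> list[str]:
    """Leaf labels of the clade ``depth`` ancestors above a leaf.

    depth 0 is the leaf itself; each increment widens the pruned clade,
    emulating the removal of increasingly deep reference information.
    The walk stops below the root so a valid tree always remains.
    """
    node = next((n for n in tree.leaves if n.label == leaf_label), None)
    if node is None:
        raise TreeError(f"unknown leaf {leaf_label!r}")
    for _ in range(depth):
        if node.parent is None or node.parent.parent is None:
            break
        node = node.parent
    return [n.label for n in node.postorder() if n.is_leaf]


def write_jplace_newick(tree: ReferenceTree, digits: int = 12) -> str:
    """Edge-numbered newick for jplace: '{edge_id}' after each length."""
    out = io.StringIO()

    def rec(node: Node) -> None:
        if node.is_leaf:
            out.write(node.label)
        else:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                rec(child)
            out.write(")")
        if node.parent is not None:
            out.write(f":{node.length:.{digits}g}{{{node.edge_id}}}")

    rec(tree.root)
    out.write(";")
    return out.getvalue()
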