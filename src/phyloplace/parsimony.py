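"""Maximum-parsimony insertion via the Fitch algorithm.

State sets over the 20-letter amino-acid alphabet are 20-bit masks;
gaps, 'X' and '*' are wildcards (the full mask) and so never force a
change.  For each branch the query attachment score is computed from
precomputed Fitch sets toward both branch ends — the Fitch length of a
binary tree is invariant under rerooting, so rooting the joined tree at
the query tip gives the textbook score without rebuilding anything.
Internal multifurcations (the anchor node of the unrooted view) are
combined pairwise in branch-id order.
"""

from __future__ import annotations

import numpy as np

from .alphabet import encode_sequence
from .msa import MSA
from .placement import InsertionScore, PlacementResult, QueryError, _rank_scores
from .tree import ReferenceTree, orient_placement_view

FULL_MASK = np.uint32((1 << 20) - 1)


def _masks(states: np.ndarray) -> np.ndarray:
    m = np.where(states >= 0, np.uint32(1) << states.astype(np.uint32), FULL_MASK)
    return m.astype(np.uint32)


def _fitch_combine(a, ca, b, cb):
    """Pairwise Fitch: intersection if non-empty else union (+1 change)."""
    inter = a & b
    empty = inter == 0
    return np.where(empty, a | b, inter), ca + cb + empty.astype(np.int64)


class ParsimonyEngine:
    """Per-branch Fitch sets toward both ends of every placement branch."""

    def __init__(self, tree: ReferenceTree, msa: MSA):
        missing = [l for l in tree.leaf_labels if l not in msa]
        if missing:
            raise QueryError(f"leaves without sequence: {missing}")
        self.tree = tree
        self.n_cols = msa.n_cols
        self.branches = tree.placement_branches()
        self.branch_by_id = {b.branch_id: b for b in self.branches}
        root, postorder, children, parent_branch = orient_placement_view(self.branches)
        self.root = root
        leaf_label = {n.index: n.label for n in tree.nodes if n.is_leaf}
        self.branch_child = {b.branch_id: v for v, b in parent_branch.items()}

        def tip_sets(v):
            if v in leaf_label:
                return _masks(encode_sequence(msa[leaf_label[v]])), np.zeros(
                    self.n_cols, dtype=np.int64
                )
            return None

        down: dict[int, np.ndarray] = {}
        dcost: dict[int, np.ndarray] = {}
        for v in postorder:
            parts = []
            own = tip_sets(v)
            if own is not None:
                parts.append(own)
            parts.extend((down[c], dcost[c]) for c, _ in children[v])
            (acc, cost), *rest = parts
            for s, c in rest:
                acc, cost = _fitch_combine(acc, cost, s, c)
            down[v], dcost[v] = acc, cost
        up: dict[int, np.ndarray] = {}
        ucost: dict[int, np.ndarray] = {}
        for u in reversed(postorder):
            for v, b in children[u]:
                parts = []
                if u == root:
                    own = tip_sets(u)
                    if own is not None:
                        parts.append(own)
                else:
                    parts.append((up[u], ucost[u]))
                parts.extend(
                    (down[s], dcost[s]) for s, _ in children[u] if s != v
                )
                (acc, cost), *rest = parts
                for s, c in rest:
                    acc, cost = _fitch_combine(acc, cost, s, c)
                up[v], ucost[v] = acc, cost
        self.down, self.dcost = down, dcost
        self.up, self.ucost = up, ucost
        # parsimony length of the reference tree itself
        self.reference_score = int(dcost[root].sum())

    def insertion_score(self, branch_id: int, query_masks: np.ndarray) -> int:
        """Fitch length of the reference tree with the query attached here."""
        v = self.branch_child[branch_id]
        sets, cost = _fitch_combine(self.down[v], self.dcost[v], self.up[v], self.ucost[v])
        extra = ((sets & query_masks) == 0).astype(np.int64)
        return int((cost + extra).sum())


def place_query_mp(
    tree: ReferenceTree, msa: MSA, query: str | np.ndarray, query_id: str = "query"
) -> PlacementResult:
    """Parsimony placement: minimal Fitch score over all branches.

    Scores are negated into the ``log_likelihood`` slot so rank 1 is
    the best (lowest-score) branch; ties go to the smallest branch id.
    """
    states = encode_sequence(query) if isinstance(query, str) else np.asarray(query)
    if states.shape[0] != msa.n_cols:
        raise QueryError(f"query row has {states.shape[0]} columns, reference has {msa.n_cols}")
    # an all-wildcard query is legal here: every branch ties at the
    # reference score and the smallest branch id is reported
    engine = ParsimonyEngine(tree, msa)
    qmasks = _masks(states)
    scores = []
    lengths = tree.edge_lengths()
    for b in engine.branches:
        sc = engine.insertion_score(b.branch_id, qmasks)
        d = 0.5 * b.length
        edge_id, edge_distal = b.to_edge_coordinates(d, lengths)
        scores.append(
            InsertionScore(
                branch_id=b.branch_id,
                log_likelihood=-float(sc),
                distal_length=d,
                proximal_length=b.length - d,
                pendant_length=0.0,
                edge_id=edge_id,
                edge_distal=edge_distal,
            )
        )
    return PlacementResult(query_id=query_id, method="MP", scores=_rank_scores(scores))
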