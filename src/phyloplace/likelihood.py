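"""Fixed-topology likelihood engine (Felsenstein pruning).

The engine works on the unrooted placement view of the reference tree
(reversible models make the likelihood independent of root position),
with alignment columns compressed to unique site patterns.  For every
placement branch it caches conditional likelihood vectors toward both
branch ends:

* ``down[b]``: probability of the data in the subtree hanging off the
  branch's distal (head) end, conditioned on the state at that end;
* ``up[b]``: probability of all remaining data, conditioned on the
  state at the proximal (tail) end.

These caches make single-branch length optimization and query insertion
cheap: neither recomputes any reference vectors.  Numerical underflow is
handled by per-node, per-pattern scaling factors accumulated in log
space (shared across rate categories so the Gamma mixture stays exact).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .alphabet import N_STATES
from .models import SubstitutionModel
from .msa import MSA
from .tree import PlacementBranch, ReferenceTree

MIN_BRANCH_LENGTH = 1e-8
MAX_BRANCH_LENGTH = 20.0
ALPHA_BOUNDS = (0.02, 100.0)


class LikelihoodError(ValueError):
    pass


def compress_patterns(encoded: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.

    Returns (patterns, weights, column_map) with ``patterns`` of shape
    (n_rows, n_patterns), integer ``weights`` summing to the column
    count, and ``column_map[c]`` the pattern index of column c.
    """
    cols = np.ascontiguousarray(encoded.T)
    uniq, col_map, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True
    )
    return uniq.T, counts.astype(float), col_map.astype(np.int64)


def _tip_partials(states: np.ndarray) -> np.ndarray:
    """(P, 20) partials for a tip: indicator rows, all-ones for missing."""
    P = np.zeros((states.shape[0], N_STATES))
    miss = states < 0
    P[np.arange(states.shape[0]), np.where(miss, 0, states)] = 1.0
    P[miss] = 1.0
    return P


class FittedReference:
    """Reference tree + model with cached per-branch partials.

    Construction performs the down/up passes; ``optimize_all`` fits the
    branch lengths and the Gamma shape.
    """

    def __init__(
        self,
        tree: ReferenceTree,
        msa: MSA,
        model: SubstitutionModel,
        compress: bool = True,
    ):
        missing = [l for l in tree.leaf_labels if l not in msa]
        if missing:
            raise LikelihoodError(f"leaves without sequence: {missing}")
        self.tree = tree
        self.msa = msa
        self.model = model
        self.leaf_order = tree.leaf_labels
        encoded = msa.encoded(self.leaf_order)
        if compress:
            self.patterns, self.weights, self.column_map = compress_patterns(encoded)
        else:
            self.patterns = encoded
            self.weights = np.ones(encoded.shape[1])
            self.column_map = np.arange(encoded.shape[1])
        self.n_patterns = self.patterns.shape[1]

        self.branches: list[PlacementBranch] = tree.placement_branches()
        self.branch_by_id = {b.branch_id: b for b in self.branches}
        self.blen: dict[int, float] = {
            b.branch_id: max(b.length, MIN_BRANCH_LENGTH) for b in self.branches
        }
        self._build_engine()
        self._tips = {
            leaf: _tip_partials(self.patterns[i]) for i, leaf in enumerate(self.leaf_order)
        }
        self.refresh()

    # ------------------------------------------------------------------
    def _build_engine(self) -> None:
        from .tree import orient_placement_view

        root, postorder, children, parent_branch = orient_placement_view(self.branches)
        self.engine_root = root
        self.postorder = postorder
        self.children = children
        self.parent_branch = parent_branch
        self.node_labels = {n.index: n.label for n in self.tree.nodes if n.is_leaf}
        # branch id -> engine child node index
        self.branch_child = {b.branch_id: v for v, b in parent_branch.items()}

    # ------------------------------------------------------------------
    def _pmats(self, t: float) -> np.ndarray:
        return self.model.transition_matrices(t)

    def _message(self, node: int, branch: PlacementBranch) -> np.ndarray:
        """down[node] pushed through the branch: (K, P, 20) at the far end."""
        Pm = self._pmats(self.blen[branch.branch_id])
        d = self.down[node]
        return d @ Pm.transpose(0, 2, 1)

    @staticmethod
    def _rescale(arr: np.ndarray, scaler: np.ndarray) -> None:
        m = arr.max(axis=(0, 2))
        m[m <= 0] = 1.0
        arr /= m[None, :, None]
        scaler += np.log(m)

    def _down_pass(self) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
        K, P = self.model.n_categories, self.n_patterns
        down: dict[int, np.ndarray] = {}
        scaler: dict[int, np.ndarray] = {}
        self.down, self.down_scaler = down, scaler
        for v in self.postorder:
            # a node seeds with its own tip partial when it is a leaf
            # (the engine anchor is a leaf on two-leaf trees)
            if v in self.node_labels:
                acc = np.broadcast_to(self._tips[self.node_labels[v]], (K, P, N_STATES)).copy()
            else:
                acc = np.ones((K, P, N_STATES))
            scal = np.zeros(P)
            for c, b in self.children[v]:
                acc *= self._message(c, b)
                scal += scaler[c]
            if self.children[v]:
                self._rescale(acc, scal)
            down[v] = acc
            scaler[v] = scal
        return down, scaler

    def _quick_root_loglik(self) -> float:
        """Root log-likelihood from a down pass only (no up caches)."""
        self._down_pass()
        return self._root_loglik()

    def refresh(self) -> None:
        """Recompute all cached vectors and the total log-likelihood."""
        K, P = self.model.n_categories, self.n_patterns
        self._down_pass()
        self.up: dict[int, np.ndarray] = {}
        self.up_scaler: dict[int, np.ndarray] = {}
        # preorder: reverse of postorder
        for u in reversed(self.postorder):
            for v, b in self.children[u]:
                if u == self.engine_root:
                    if u in self.node_labels:
                        acc = np.broadcast_to(
                            self._tips[self.node_labels[u]], (K, P, N_STATES)
                        ).copy()
                    else:
                        acc = np.ones((K, P, N_STATES))
                    scal = np.zeros(P)
                else:
                    pb = self.parent_branch[u]
                    Pm = self._pmats(self.blen[pb.branch_id])
                    acc = self.up[u] @ Pm.transpose(0, 2, 1)
                    scal = self.up_scaler[u].copy()
                for s, sb in self.children[u]:
                    if s == v:
                        continue
                    acc = acc * self._message(s, sb)
                    scal = scal + self.down_scaler[s]
                self._rescale(acc, scal)
                self.up[v] = acc
                self.up_scaler[v] = scal
        self.log_likelihood_value = self._root_loglik()

    def _root_loglik(self) -> float:
        root = self.engine_root
        site = (
            np.einsum("kpi,i->p", self.down[root], self.model.pi)
            / self.model.n_categories
        )
        return float(np.dot(self.weights, np.log(site) + self.down_scaler[root]))

    # ------------------------------------------------------------------
    def branch_loglik(self, branch_id: int, t: float | None = None) -> float:
        """Log-likelihood evaluated across one branch (virtual root there)."""
        v = self.branch_child[branch_id]
        t = self.blen[branch_id] if t is None else t
        Pm = self.model.transition_matrices(t)
        below = self.down[v] @ Pm.transpose(0, 2, 1)
        site = (
            np.einsum("kpi,kpi,i->p", self.up[v], below, self.model.pi)
            / self.model.n_categories
        )
        site = np.maximum(site, 1e-300)
        return float(
            np.dot(self.weights, np.log(site) + self.down_scaler[v] + self.up_scaler[v])
        )

    def optimize_branch_length(self, branch_id: int) -> float:
        """1-D bounded optimization of one branch length; never worsens logL."""
        current = self.blen[branch_id]
        f = lambda t: -self.branch_loglik(branch_id, t)
        res = minimize_scalar(
            f,
            bounds=(MIN_BRANCH_LENGTH, MAX_BRANCH_LENGTH),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if -res.fun >= self.branch_loglik(branch_id, current):
            self.blen[branch_id] = float(res.x)
        self.refresh()
        return self.blen[branch_id]

    # ------------------------------------------------------------------
    def sync_tree(self) -> None:
        """Write optimized branch lengths back onto the ReferenceTree.

        The merged root branch length is split over the two rooted edges
        in their original proportion (the model cannot locate the root).
        """
        for b in self.branches:
            t = self.blen[b.branch_id]
            if len(b.edges) == 1:
                b.head.length = t
            else:
                total = b.head.length + b.tail.length
                frac = b.head.length / total if total > 0 else 0.5
                b.head.length = t * frac
                b.tail.length = t * (1.0 - frac)


    def save(self, directory) -> None:
        """Serialize the fitted state (tree with optimized lengths + alpha)."""
        import json
        from pathlib import Path

        from .tree import write_newick

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.sync_tree()
        (d / "fitted_tree.nwk").write_text(write_newick(self.tree) + "\n")
        (d / "fitted.json").write_text(
            json.dumps(
                {
                    "model": self.model.name,
                    "alpha": self.model.alpha,
                    "log_likelihood": self.log_likelihood_value,
                },
                indent=2,
            )
            + "\n"
        )


def log_likelihood(tree: ReferenceTree, msa: MSA, model: SubstitutionModel, compress: bool = True) -> float:
    """Total log-likelihood (nats) of the alignment on the tree."""
    return FittedReference(tree, msa, model, compress=compress).log_likelihood_value


def optimize_all(
    tree: ReferenceTree,
    msa: MSA,
    model: SubstitutionModel,
    estimate_alpha: bool = True,
    tol: float = 1e-4,
    max_sweeps: int = 100,
) -> FittedReference:
    """Fit all branch lengths (and optionally the Gamma shape).

    Repeated coordinate sweeps — every branch by bounded 1-D search,
    then alpha in [0.02, 100] — until the sweep improves the total
    log-likelihood by less than ``tol``.  The log-likelihood is
    non-decreasing across sweeps by construction.  The input tree is
    never modified: the fitted lengths live on an internal copy.
    """
    fit = FittedReference(tree.copy(), msa, model)
    trace = [fit.log_likelihood_value]
    for _ in range(max_sweeps):
        before = fit.log_likelihood_value
        for b in fit.branches:
            fit.optimize_branch_length(b.branch_id)
        if estimate_alpha and model.n_categories > 1:
            fit = _optimize_alpha(fit)
        after = fit.log_likelihood_value
        trace.append(after)
        if after - before < tol:
            fit.sync_tree()
            return fit
    raise LikelihoodError(
        f"branch-length optimization did not converge in {max_sweeps} sweeps; trace={trace}"
    )


def _optimize_alpha(fit: FittedReference) -> FittedReference:
    base = fit.log_likelihood_value
    original_alpha = fit.model.alpha

    def neg(alpha: float) -> float:
        fit.model = fit.model.with_alpha(float(alpha))
        return -fit._quick_root_loglik()

    res = minimize_scalar(neg, bounds=ALPHA_BOUNDS, method="bounded", options={"xatol": 1e-4})
    chosen = float(res.x) if -res.fun >= base else original_alpha
    fit.model = fit.model.with_alpha(chosen)
    fit.refresh()
    return fit
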