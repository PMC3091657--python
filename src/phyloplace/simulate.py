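"""Synthetic reference packages and queries with known truth.

Random bifurcating topologies (sequential random attachment),
exponential branch lengths (mean 0.1 substitutions/site), sequence
evolution under the reversible amino-acid model with per-site
discrete-Gamma rate categories, queries planted on known branches, and
back-translated "genomes" embedding marker genes in random intergenic
sequence.  Every operation is a pure function of (inputs, seed):
``evolve_alignment`` and ``plant_query`` with the same (tree, model,
length, seed) share one evolutionary realization, so planted queries
are genuinely homologous to the reference rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import N_STATES, decode_states
from .models import SubstitutionModel, load_empirical_model
from .msa import MSA
from .refpkg import N_RANKS, RefPackage
from .tree import Node, ReferenceTree

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic reference package."""

    n_leaves: int = 20
    mean_branch_length: float = 0.1
    n_cols: int = 300
    model_name: str = "WAG"
    alpha: float = 1.0
    seed: int = 0
    pendant_length: float = 0.05
    n_markers: int = 1
    marker_length: int = 300

    def __post_init__(self):
        if self.n_leaves < 3 or self.n_cols < 1 or self.mean_branch_length <= 0:
            raise ValueError("simulation parameters must be positive (>= 3 leaves)")


def random_tree(n_leaves: int, seed: int, mean_branch_length: float = 0.1) -> ReferenceTree:
    """Random unrooted bifurcating topology with exponential lengths.

    Built by sequential random attachment: starting from a 3-leaf star,
    each new leaf splits a uniformly chosen existing edge.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    labels = [f"t{i+1}" for i in range(n_leaves)]
    root = Node()
    edges: list[Node] = []  # nodes whose parent edge can be split
    for lab in labels[:3]:
        edges.append(root.add(Node(lab)))
    for lab in labels[3:]:
        target = edges[rng.integers(0, len(edges))]
        parent = target.parent
        mid = Node()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        mid.add(target)
        leaf = mid.add(Node(lab))
        edges.extend([mid, leaf])
    tree = ReferenceTree(root)
    for node in tree.edge_nodes:
        node.length = float(rng.exponential(mean_branch_length))
    return ReferenceTree(tree.root)


def _site_categories(model: SubstitutionModel, length: int, rng) -> np.ndarray:
    return rng.integers(0, model.n_categories, size=length)


def _evolve_states(parent_states, cats, t, model, rng):
    """Child states given parent states, per-site rate categories."""
    out = np.empty_like(parent_states)
    for k in range(model.n_categories):
        idx = np.flatnonzero(cats == k)
        if idx.size == 0:
            continue
        P = model.transition_matrix(t, model.rates[k])
        cum = np.cumsum(P, axis=1)
        u = rng.random(idx.size)
        rows = cum[parent_states[idx]]
        out[idx] = (rows >= u[:, None]).argmax(axis=1)
    return out


def _simulate_node_states(tree: ReferenceTree, model: SubstitutionModel, length: int, rng):
    """States at every tree node plus per-site categories (one realization)."""
    cats = _site_categories(model, length, rng)
    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[root.index] = rng.choice(N_STATES, size=length, p=model.pi)
    for node in _preorder(root):
        if node.parent is not None:
            states[node.index] = _evolve_states(
                states[node.parent.index], cats, node.length, model, rng
            )
    return states, cats


def _preorder(root: Node):
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def evolve_alignment(tree: ReferenceTree, model: SubstitutionModel, length: int, seed: int) -> MSA:
    """Simulate an ungapped alignment down the tree (root states from pi)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    states, _ = _simulate_node_states(tree, model, length, rng)
    return MSA({n.label: decode_states(states[n.index]) for n in tree.leaves})


def plant_query(
    tree: ReferenceTree,
    model: SubstitutionModel,
    branch_id: int,
    pendant: float,
    length: int,
    seed: int,
    query_seed: int | None = None,
) -> tuple[str, int]:
    """Evolve a query from the midpoint of a branch along a pendant edge.

    ``seed`` must match the ``evolve_alignment(tree, model, length,
    seed)`` call that produced the reference alignment: the internal
    node states are re-derived from that same stream, so the query is
    genuinely homologous to the reference rows.  ``query_seed`` (default
    ``seed``) varies only the bridge/pendant randomness, allowing many
    independent queries against one reference realization.  Returns
    (query peptide, true placement-branch id).
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    rng_tree = np.random.default_rng(ss[0])
    states, cats = _simulate_node_states(tree, model, length, rng_tree)
    branch = {b.branch_id: b for b in tree.placement_branches()}.get(branch_id)
    if branch is None:
        raise ValueError(f"unknown placement branch {branch_id}")
    qs = seed if query_seed is None else query_seed
    rng_q = np.random.default_rng(np.random.SeedSequence(qs).spawn(2)[1])
    # midpoint states are a bridge conditioned on BOTH branch ends, so
    # the query truly hangs off the middle of this branch
    head = branch.head
    tail = head.parent if len(branch.edges) == 1 else branch.tail
    mid = _bridge_states(
        states[tail.index], states[head.index], branch.length, cats, model, rng_q
    )
    if pendant > 0:
        q = _evolve_states(mid, cats, pendant, model, rng_q)
    else:
        q = mid
    return decode_states(q), branch_id


def _bridge_states(a_states, b_states, t_total, cats, model, rng):
    """Sample the state halfway along a branch given both endpoint states."""
    length = a_states.shape[0]
    out = np.empty_like(a_states)
    half = 0.5 * t_total
    for k in range(model.n_categories):
        idx = np.flatnonzero(cats == k)
        if idx.size == 0:
            continue
        P = model.transition_matrix(half, model.rates[k])
        w = P[a_states[idx]] * P[:, b_states[idx]].T  # (m, 20)
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random(idx.size)
        out[idx] = (np.cumsum(w, axis=1) >= u[:, None]).argmax(axis=1)
    return out


def _clade_label(node: Node, rank: int) -> str:
    # ancestor at depth rank+1 from the root determines the rank label
    chain = []
    n = node
    while n is not None:
        chain.append(n)
        n = n.parent
    chain.reverse()  # root ... leaf
    anchor = chain[min(rank + 1, len(chain) - 1)]
    return f"r{rank}n{anchor.index}"


def synthetic_taxonomy(tree: ReferenceTree) -> dict[str, tuple[str, ...]]:
    """Lineages derived from tree structure: two leaves agree at rank k
    exactly when they share the ancestor k+1 steps below the root."""
    return {
        leaf.label: tuple(_clade_label(leaf, r) for r in range(N_RANKS))
        for leaf in tree.leaves
    }


def simulate_reference_package(cfg: SimConfig) -> RefPackage:
    """Random tree + simulated alignment + structure-derived taxonomy."""
    tree = random_tree(cfg.n_leaves, cfg.seed, cfg.mean_branch_length)
    model = load_empirical_model(cfg.model_name, alpha=cfg.alpha) \
        if cfg.model_name.upper() != "UNIFORM" else _uniform(cfg.alpha)
    msa = evolve_alignment(tree, model, cfg.n_cols, cfg.seed)
    return RefPackage(
        tree=tree,
        msa=msa,
        taxonomy=synthetic_taxonomy(tree),
        model_name=cfg.model_name,
        alpha=cfg.alpha,
        name=f"sim{cfg.seed}",
    )


def _uniform(alpha: float):
    from .models import uniform_model

    return uniform_model(alpha=alpha, n_categories=4)


# ----------------------------------------------------------------------
# genomes


def back_translate(peptide: str, rng) -> str:
    """Uniform synonymous codon choice per residue."""
    return "".join(_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in peptide)


@dataclass(frozen=True)
class MarkerLocation:
    marker: str
    start: int  # 0-based, on the forward strand
    end: int  # exclusive
    strand: int  # +1 / -1
    frame: int  # six-frame index recovering the peptide
    peptide: str


def synth_genome(
    markers: dict[str, str], spacer_nt: int, seed: int
) -> tuple[str, list[MarkerLocation]]:
    """Random "genome": back-translated markers separated by random spacers.

    Markers land on random strands; metadata records coordinates and
    the six-frame index whose translation recovers each peptide.
    """
    if not markers:
        raise ValueError("need at least one marker peptide")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    locs: list[MarkerLocation] = []
    pos = 0

    def spacer() -> str:
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=spacer_nt))
        return s

    for name, pep in markers.items():
        s = spacer()
        parts.append(s)
        pos += len(s)
        cds = back_translate(pep, rng)
        strand = 1 if rng.random() < 0.5 else -1
        if strand < 0:
            cds = cds[::-1].translate(_COMPLEMENT)
        start, end = pos, pos + len(cds)
        parts.append(cds)
        pos = end
        locs.append(MarkerLocation(name, start, end, strand, 0, pep))
    s = spacer()
    parts.append(s)
    genome = "".join(parts)
    final = []
    for loc in locs:
        if loc.strand > 0:
            frame = loc.start % 3 + 1
        else:
            frame = -((len(genome) - loc.end) % 3 + 1)
        final.append(MarkerLocation(loc.marker, loc.start, loc.end, loc.strand, frame, loc.peptide))
    return genome, final


def bootstrap_distinct_fraction(n_columns: int, n_replicates: int, seed: int) -> float:
    """Mean percentage of distinct columns drawn per bootstrap replicate.

    Sampling n columns with replacement uses on average
    100*(1 - (1 - 1/n)^n) percent distinct columns (~63.2% for large n).
    """
    if n_columns < 1 or n_replicates < 1:
        raise ValueError("need n >= 1 columns and >= 1 replicates")
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_replicates)
    for i in range(n_replicates):
        draw = rng.integers(0, n_columns, size=n_columns)
        fracs[i] = np.unique(draw).size / n_columns
    return float(fracs.mean() * 100.0)
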